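"""Procedural voxel geometries: canonical bifurcation and straight cylinders.

The study domain is an idealised vascular junction: a straight main
channel of length ten radii along +x with a side branch of length five
radii leaving the main-channel midpoint at a configurable angle
(default 45 degrees), all cross-sections circular with constant radius.
The continuous solid is the union of capped cylinders; a lattice site is
fluid iff its centre is strictly inside that union laterally (the cap
planes themselves are included so that inlet/outlet sites sit exactly on
their capping planes).

Besides the classified site lattice the builder derives everything the
solver and the quantities of interest need: per-link wall-distance
fractions ``q`` for the interpolated (Bouzidi) wall rule, inlet/outlet
link registries, a parabolic inlet weight map and ordered centreline
site lists for both branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .lbm_core import C

# site_type codes
SOLID = 0
FLUID = 1
WALL_ADJACENT = 2
INLET = 3
OUTLET0 = 4
OUTLET1 = 5

_BISECT_ITERS = 60  # halves the bracket to ~1e-18 < the 1e-10 tolerance


@dataclass(frozen=True)
class BifurcationSpec:
    """Parameters of the canonical bifurcation (lattice units).

    radius
        Vessel radius in lattice units (e.g. 20 for the coarse study).
    arm_length_factor
        Arm length as a multiple of the radius (default 5, giving a main
        channel of 10 radii).
    branch_angle_deg
        Angle between the side branch and the downstream +x direction.
    include_branch
        When False a plain straight cylinder is built.
    """

    radius: float
    arm_length_factor: float = 5.0
    branch_angle_deg: float = 45.0
    include_branch: bool = True

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError("radius must be positive")
        if self.arm_length_factor <= 0:
            raise GeometryError("arm_length_factor must be positive")
        if self.include_branch and not (0.0 < self.branch_angle_deg < 90.0):
            raise GeometryError("branch angle must lie strictly between 0 and 90 deg")

    @property
    def main_length(self) -> int:
        """Main-channel length in lattice units (two arms of 5 radii)."""
        return int(round(2.0 * self.arm_length_factor * self.radius))

    @property
    def branch_length(self) -> float:
        return self.arm_length_factor * self.radius


def cylinder_spec(radius: float, length: float) -> BifurcationSpec:
    """Spec for a straight cylinder of a given total length (no branch)."""
    return BifurcationSpec(
        radius=radius,
        arm_length_factor=length / (2.0 * radius),
        include_branch=False,
    )


@dataclass(frozen=True)
class ChannelUnion:
    """Continuous implicit description of the capped-cylinder union."""

    x0: float
    length: float
    centre: float          # common y and z of the main axis
    radius: float
    has_branch: bool
    p0: np.ndarray         # branch origin (junction, on the main axis)
    d: np.ndarray          # branch unit direction
    branch_length: float

    def inside(self, pts) -> np.ndarray:
        """Strictly-inside-laterally, closed-at-caps membership test.

        ``pts`` is (..., 3); returns a boolean array of the leading shape.
        A 1e-9 guard band on the squared radius makes the strict
        inequality robust to rounding for site centres that fall exactly
        on the lateral surface (they count as solid).
        """
        pts = np.asarray(pts, dtype=float)
        x = pts[..., 0]
        y = pts[..., 1]
        z = pts[..., 2]
        r2max = self.radius**2 - 1e-9
        r2 = (y - self.centre) ** 2 + (z - self.centre) ** 2
        m = (x >= self.x0) & (x <= self.x0 + self.length) & (r2 < r2max)
        if self.has_branch:
            rel = pts - self.p0
            s = rel @ self.d
            rad2 = (rel * rel).sum(axis=-1) - s * s
            m = m | ((s >= 0.0) & (s <= self.branch_length) & (rad2 < r2max))
        return m

    def branch_axial(self, pts) -> np.ndarray:
        """Coordinate along the branch axis measured from the junction."""
        return (np.asarray(pts, dtype=float) - self.p0) @ self.d


@dataclass
class VoxelDomain:
    """Classified lattice plus the registries derived from it.

    Site indices (`slots`) refer to rows of ``fluid_idx`` which lists the
    (i, j, k) coordinates of the fluid sites in lexicographic order; the
    physical position of site (i, j, k) is its centre, offset so that
    the inlet plane is at x-index ``inlet_x``.
    """

    spec: BifurcationSpec | None
    shape: tuple[int, int, int]
    site_type: np.ndarray              # 3D uint8
    fluid_idx: np.ndarray              # (n_fluid, 3) int
    fluid_slot: np.ndarray             # 3D int32, -1 for solid
    channels: ChannelUnion | None
    inlet_x: int
    axis_centre: int
    # boundary link registries: parallel arrays (site slot, direction index)
    wall_site: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    wall_dir: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    wall_q: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    inlet_link_site: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    inlet_link_dir: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    outlet_link_site: dict = field(default_factory=dict)   # outlet id -> slots
    outlet_link_dir: dict = field(default_factory=dict)
    # site registries
    inlet_sites: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    inlet_weights: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    outlet_sites: dict = field(default_factory=dict)
    inlet_normal: np.ndarray = field(default_factory=lambda: np.array([-1, 0, 0]))
    outlet_normals: dict = field(default_factory=dict)
    main_axis_sites: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    branch_axis_sites: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    periodic: bool = False

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_idx.shape[0])

    def site_positions(self, slots) -> np.ndarray:
        return self.fluid_idx[np.asarray(slots, dtype=np.int64)].astype(float)


def _target_is_fluid(fluid: np.ndarray, c) -> np.ndarray:
    """For each site, whether the site at +c is in-bounds and fluid."""
    out = np.zeros_like(fluid)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(c):
        n = fluid.shape[ax]
        if step == 1:
            dst[ax] = slice(0, n - 1)
            src[ax] = slice(1, n)
        elif step == -1:
            dst[ax] = slice(1, n)
            src[ax] = slice(0, n - 1)
    out[tuple(dst)] = fluid[tuple(src)]
    return out


def _bisect_q(channels: ChannelUnion, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Fraction of each fluid->solid link cut by the continuous surface.

    Bisection on the implicit membership function along the unit link;
    the fluid end is inside, the target end outside by construction.
    """
    points = points.astype(float)
    step = C[dirs].astype(float)
    if np.any(channels.inside(points + step)):
        raise GeometryError("no sign change along a link flagged fluid->solid")
    lo = np.zeros(len(points))
    hi = np.ones(len(points))
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        ins = channels.inside(points + mid[:, None] * step)
        lo = np.where(ins, mid, lo)
        hi = np.where(ins, hi, mid)
    return 0.5 * (lo + hi)


def compute_wall_distances(domain: VoxelDomain, channels: ChannelUnion | None = None):
    """Recompute wall-distance fractions for every wall link of ``domain``.

    Returns (site slots, direction indices, q) with q in (0, 1] found to
    well below 1e-10 by bisection on the implicit solid description.
    """
    channels = channels or domain.channels
    if channels is None:
        raise GeometryError("domain has no continuous solid description")
    pts = domain.fluid_idx[domain.wall_site].astype(float)
    q = _bisect_q(channels, pts, domain.wall_dir)
    return domain.wall_site, domain.wall_dir, q


def compute_inlet_weights(domain: VoxelDomain) -> np.ndarray:
    """Parabolic inlet weight map: w = max(0, 1 - (r/R)^2).

    ``r`` is the in-plane distance of each inlet site from the continuous
    centreline, ``R`` the continuous radius; the profile peaks at 1 on
    the axis and is clamped to 0 at (or beyond) the wall.
    """
    if domain.inlet_sites.size == 0:
        raise GeometryError("domain has no inlet sites")
    c = domain.axis_centre
    R = domain.channels.radius
    pos = domain.fluid_idx[domain.inlet_sites]
    r2 = (pos[:, 1] - c) ** 2 + (pos[:, 2] - c) ** 2
    return np.maximum(0.0, 1.0 - r2 / R**2)


def _chain_6connected(sites: np.ndarray) -> np.ndarray:
    """Complete a dedeuplicated nearest-site sequence into a 6-connected chain.

    Consecutive sites differ by at most one in each coordinate; diagonal
    moves are split into unit axis steps (x, then y, then z).
    """
    out = [sites[0]]
    for nxt in sites[1:]:
        cur = out[-1].copy()
        for ax in range(3):
            while cur[ax] != nxt[ax]:
                cur = cur.copy()
                cur[ax] += 1 if nxt[ax] > cur[ax] else -1
                out.append(cur)
    return np.array(out)


def _centreline_sites(start: np.ndarray, direction: np.ndarray, length: float,
                      fluid_slot: np.ndarray) -> np.ndarray:
    """Ordered fluid slots tracking a continuous centreline segment."""
    ts = np.arange(0.0, length + 1e-9, 0.05)
    pts = start[None, :] + ts[:, None] * direction[None, :]
    sites = np.rint(pts).astype(np.int64)
    keep = np.ones(len(sites), dtype=bool)
    keep[1:] = (sites[1:] != sites[:-1]).any(axis=1)
    sites = sites[keep]
    sites = _chain_6connected(sites)
    slots = fluid_slot[sites[:, 0], sites[:, 1], sites[:, 2]]
    # rounding can step past a cap plane at the very ends; trim those
    good = slots >= 0
    if good.any():
        first, last = np.flatnonzero(good)[[0, -1]]
        slots = slots[first:last + 1]
    if np.any(slots < 0):
        raise GeometryError("centreline leaves the fluid region")
    return slots.astype(np.int64)


def extract_centreline_sites(domain: VoxelDomain, which: str) -> np.ndarray:
    """Ordered centreline slots, inlet->outlet (main) or junction->outlet (branch)."""
    if which == "main":
        return domain.main_axis_sites
    if which == "branch":
        return domain.branch_axis_sites
    raise ValueError(f"unknown branch label {which!r}")


def build_bifurcation(spec: BifurcationSpec) -> VoxelDomain:
    """Voxelise the canonical bifurcation (or a straight cylinder).

    The main channel runs along +x from the inlet plane to outlet 1; the
    side branch (outlet 0) leaves the main-channel midpoint at
    ``branch_angle_deg`` in the x-y plane.  Deterministic: identical
    specs produce bitwise-identical domains.
    """
    R = float(spec.radius)
    if R < 2.0:
        raise GeometryError("unresolvable lumen: radius below 2 lattice units")
    L = spec.main_length
    Lb = spec.branch_length
    x0 = 1
    c = int(math.ceil(R)) + 1
    ang = math.radians(spec.branch_angle_deg)
    d = np.array([math.cos(ang), math.sin(ang), 0.0])
    p0 = np.array([x0 + L / 2.0, float(c), float(c)])

    if spec.include_branch:
        # the branch end disc must stay clear of the outlet cap plane
        end_max_x = p0[0] + Lb * d[0] + R * abs(d[1])
        if end_max_x >= x0 + L - 1.0:
            raise GeometryError("branch overlaps the outlet end cap")

    nx = x0 + L + 2
    ny = 2 * c + 1
    if spec.include_branch:
        ny = max(ny, int(math.ceil(p0[1] + Lb * d[1] + R)) + 2)
    nz = 2 * c + 1
    shape = (nx, ny, nz)

    channels = ChannelUnion(
        x0=float(x0), length=float(L), centre=float(c), radius=R,
        has_branch=spec.include_branch, p0=p0, d=d, branch_length=float(Lb),
    )

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).astype(float)
    fluid = channels.inside(pts)

    fluid_idx = np.argwhere(fluid).astype(np.int64)
    n_fluid = len(fluid_idx)
    fluid_slot = np.full(shape, -1, dtype=np.int64)
    fluid_slot[fluid] = np.arange(n_fluid)

    wall_site, wall_dir = [], []
    inlet_site, inlet_dir = [], []
    out_site = {0: [], 1: []}
    out_dir = {0: [], 1: []}

    for q_dir in range(1, 19):
        cv = C[q_dir]
        tgt_fluid = _target_is_fluid(fluid, cv)
        bnd = fluid & ~tgt_fluid
        coords = np.argwhere(bnd)
        if coords.size == 0:
            continue
        slots = fluid_slot[coords[:, 0], coords[:, 1], coords[:, 2]]
        targets = coords + cv
        tx = targets[:, 0]
        is_in = tx < x0
        is_o1 = tx > x0 + L
        if spec.include_branch:
            s_t = channels.branch_axial(targets.astype(float))
            rel = targets.astype(float) - p0
            rad2 = (rel * rel).sum(axis=1) - s_t * s_t
            is_o0 = (~is_in) & (~is_o1) & (s_t > Lb) & (rad2 < (R + 1.0) ** 2)
        else:
            is_o0 = np.zeros(len(coords), dtype=bool)
        is_wall = ~(is_in | is_o1 | is_o0)

        inlet_site.append(slots[is_in])
        inlet_dir.append(np.full(is_in.sum(), q_dir, np.int64))
        out_site[1].append(slots[is_o1])
        out_dir[1].append(np.full(is_o1.sum(), q_dir, np.int64))
        out_site[0].append(slots[is_o0])
        out_dir[0].append(np.full(is_o0.sum(), q_dir, np.int64))
        wall_site.append(slots[is_wall])
        wall_dir.append(np.full(is_wall.sum(), q_dir, np.int64))

    def _cat(parts, dtype=np.int64):
        return (np.concatenate(parts) if parts else np.empty(0, dtype)).astype(dtype)

    wall_site = _cat(wall_site)
    wall_dir = _cat(wall_dir)
    inlet_site = _cat(inlet_site)
    inlet_dir = _cat(inlet_dir)
    for o in (0, 1):
        out_site[o] = _cat(out_site[o])
        out_dir[o] = _cat(out_dir[o])

    dom = VoxelDomain(
        spec=spec, shape=shape, site_type=np.zeros(shape, np.uint8),
        fluid_idx=fluid_idx, fluid_slot=fluid_slot, channels=channels,
        inlet_x=x0, axis_centre=c,
        wall_site=wall_site, wall_dir=wall_dir,
        inlet_link_site=inlet_site, inlet_link_dir=inlet_dir,
        outlet_link_site=out_site, outlet_link_dir=out_dir,
    )

    _, _, dom.wall_q = compute_wall_distances(dom, channels)

    # site registries and type labels (boundary labels take precedence
    # over the wall-adjacent label, which takes precedence over plain fluid)
    st = dom.site_type
    st[fluid] = FLUID
    for slots, code in ((wall_site, WALL_ADJACENT),):
        pos = fluid_idx[np.unique(slots)] if slots.size else np.empty((0, 3), np.int64)
        st[pos[:, 0], pos[:, 1], pos[:, 2]] = code
    dom.inlet_sites = np.unique(inlet_site)
    dom.outlet_sites = {o: np.unique(out_site[o]) for o in (0, 1)}
    for slots, code in (
        (dom.inlet_sites, INLET),
        (dom.outlet_sites[0], OUTLET0),
        (dom.outlet_sites[1], OUTLET1),
    ):
        pos = fluid_idx[slots] if slots.size else np.empty((0, 3), np.int64)
        st[pos[:, 0], pos[:, 1], pos[:, 2]] = code

    dom.inlet_weights = compute_inlet_weights(dom)
    dom.inlet_normal = np.array([-1, 0, 0])
    dom.outlet_normals = {1: np.array([1.0, 0.0, 0.0])}
    if spec.include_branch:
        dom.outlet_normals[0] = d.copy()

    dom.main_axis_sites = _centreline_sites(
        np.array([float(x0), float(c), float(c)]), np.array([1.0, 0.0, 0.0]),
        float(L), fluid_slot,
    )
    if spec.include_branch:
        dom.branch_axis_sites = _centreline_sites(p0, d, float(Lb), fluid_slot)
    return dom


def periodic_box(shape: tuple[int, int, int]) -> VoxelDomain:
    """Fully periodic all-fluid box (verification domain, no boundaries)."""
    shape = tuple(int(n) for n in shape)
    fluid = np.ones(shape, dtype=bool)
    fluid_idx = np.argwhere(fluid).astype(np.int64)
    fluid_slot = np.arange(fluid_idx.shape[0], dtype=np.int64).reshape(shape)
    return VoxelDomain(
        spec=None, shape=shape,
        site_type=np.full(shape, FLUID, np.uint8),
        fluid_idx=fluid_idx, fluid_slot=fluid_slot, channels=None,
        inlet_x=0, axis_centre=0, periodic=True,
    )
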