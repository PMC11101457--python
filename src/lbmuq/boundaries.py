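"""Boundary closures: Ladd velocity inlet, phantom-site pressure outlet,
Bouzidi interpolated walls, and the time programs that drive them.

All three schemes close the same gap: after streaming, populations whose
source lies outside the fluid are unknown and must be reconstructed.

* Walls use the Bouzidi rule — simple bounce-back linearly interpolated
  with the wall at fractional link distance ``q``; at ``q = 1/2`` it
  reduces exactly to bounce-back.  Wall velocity is zero.
* Velocity inlets use the Ladd rule: bounce-back plus the correction
  ``-2 w_i rho u.c_i / Cs^2`` imposing the target fluid velocity, here a
  parabolic profile scaled by a maximum-velocity program.
* Pressure outlets follow the phantom-site construction: the unknown
  inbound populations are the equilibrium populations of a fictitious
  site holding the imposed density and the boundary site's own normal
  velocity component (tangential components zero) — a mixed
  Dirichlet-Neumann condition, first-order accurate.

The sinusoidal outlet program is
``p(t) = mean + amplitude * sin(2 pi t / period + phase)`` — the four
named parameters fix only the family; this sine-with-phase-offset
convention is this package's documented choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, StabilityError
from .geometry import VoxelDomain
from .lbm_core import C, CS, OPPOSITE, Q, W

_CF = C.astype(float)


# ---------------------------------------------------------------- programs

@dataclass(frozen=True)
class SinusoidalPressure:
    """Sinusoidal pressure program (mmHg, s, rad)."""

    mean: float
    amplitude: float = 0.0
    period: float = 1.0
    phase: float = 0.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def value(self, t: float) -> float:
        return self.mean + self.amplitude * math.sin(
            2.0 * math.pi * t / self.period + self.phase
        )


def waveform_value(bc: SinusoidalPressure, t: float) -> float:
    """Pressure (mmHg) of the sinusoidal program at time ``t`` (s)."""
    return bc.value(t)


@dataclass(frozen=True)
class ConstantInlet:
    """Constant peak inlet velocity (m/s), optionally half-cosine ramped.

    A short ramp from rest suppresses the acoustic transient a step
    start would launch; the steady state is unaffected.
    """

    peak: float
    ramp_duration: float = 0.0

    def __post_init__(self):
        if self.peak < 0 or self.ramp_duration < 0:
            raise ValueError("peak and ramp_duration must be non-negative")

    def value(self, t: float) -> float:
        if self.ramp_duration > 0 and t < self.ramp_duration:
            return self.peak * 0.5 * (1.0 - math.cos(math.pi * t / self.ramp_duration))
        return self.peak


@dataclass(frozen=True)
class TransientInlet:
    """Ramped initialisation followed by a single-peak pulse.

    Emulates a transient maximum-velocity program: a half-cosine ramp
    from rest to ``base`` over ``ramp_duration``, then a smooth sin^2
    pulse up to ``peak`` over ``[pulse_start, pulse_start + pulse_duration]``,
    then back to ``base``.
    """

    base: float
    peak: float
    ramp_duration: float
    pulse_start: float
    pulse_duration: float

    def __post_init__(self):
        if min(self.base, self.peak, self.ramp_duration, self.pulse_duration) < 0:
            raise ValueError("all program parameters must be non-negative")
        if self.pulse_start < self.ramp_duration:
            raise ValueError("pulse must start after the initialisation ramp")

    def value(self, t: float) -> float:
        if t < self.ramp_duration:
            return self.base * 0.5 * (1.0 - math.cos(math.pi * t / self.ramp_duration))
        if self.pulse_start <= t < self.pulse_start + self.pulse_duration:
            s = (t - self.pulse_start) / self.pulse_duration
            return self.base + (self.peak - self.base) * math.sin(math.pi * s) ** 2
        return self.base


# ---------------------------------------------------- compiled link tables

@dataclass
class OutletTable:
    """Per-outlet phantom-site reconstruction table."""

    dst: np.ndarray        # flat slots (dir*n + site) receiving the phantom feq
    site: np.ndarray       # fluid slot of the boundary site
    cdotn: np.ndarray      # c_idir . outward normal, per link
    w: np.ndarray          # lattice weight of the reconstructed direction
    normal: np.ndarray     # outward unit normal (3,)


@dataclass
class LinkTables:
    """Precompiled streaming schedule for one voxel domain.

    ``pull_src`` realises the pull-scheme streaming as a single gather;
    slots fed by a boundary closure are subsequently overwritten by the
    apply_* functions below.
    """

    n_fluid: int
    pull_src: np.ndarray
    bz_dst: np.ndarray
    bz_a: np.ndarray
    bz_b: np.ndarray
    bz_ca: np.ndarray
    bz_cb: np.ndarray
    in_dst: np.ndarray
    in_a: np.ndarray
    in_site: np.ndarray
    in_coeff: np.ndarray
    outlets: dict = field(default_factory=dict)


def compile_link_tables(domain: VoxelDomain) -> LinkTables:
    """Turn a domain's link registries into flat gather/scatter tables."""
    n = domain.n_fluid
    idx = domain.fluid_idx
    slot3 = domain.fluid_slot
    shape = domain.shape

    pull_src = np.arange(Q * n, dtype=np.int64)
    for i in range(1, Q):
        src = idx - C[i]
        if domain.periodic:
            src = src % np.array(shape)
            ok = np.ones(n, dtype=bool)
        else:
            ok = np.all((src >= 0) & (src < np.array(shape)), axis=1)
        sslot = np.full(n, -1, dtype=np.int64)
        sslot[ok] = slot3[src[ok, 0], src[ok, 1], src[ok, 2]]
        good = sslot >= 0
        pull_src[i * n + np.flatnonzero(good)] = i * n + sslot[good]

    # Bouzidi wall links
    s = domain.wall_site
    j = domain.wall_dir
    qq = domain.wall_q
    if np.any((qq <= 0.0) | (qq > 1.0)):
        raise GeometryError("wall-distance fraction outside (0, 1]")
    dst = OPPOSITE[j] * n + s
    near = qq < 0.5
    a = j * n + s
    ca = np.where(near, 2.0 * qq, 1.0 / (2.0 * qq))
    # upstream neighbour (away from the wall) for the q < 1/2 branch
    up = idx[s] - C[j]
    ok = np.all((up >= 0) & (up < np.array(shape)), axis=1)
    upslot = np.full(len(s), -1, dtype=np.int64)
    upslot[ok] = slot3[up[ok, 0], up[ok, 1], up[ok, 2]]
    have_up = upslot >= 0
    b = np.where(near & have_up, j * n + upslot, OPPOSITE[j] * n + s)
    cb = np.where(near, np.where(have_up, 1.0 - 2.0 * qq, 0.0),
                  1.0 - 1.0 / (2.0 * qq))
    # thin-gap fallback: no upstream fluid neighbour -> plain bounce-back
    ca = np.where(near & ~have_up, 1.0, ca)

    # inlet links (Ladd): coefficient of u_max(t) * rho(site)
    s_in = domain.inlet_link_site
    j_in = domain.inlet_link_dir
    in_dst = OPPOSITE[j_in] * n + s_in
    in_a = j_in * n + s_in
    n_in = -domain.inlet_normal.astype(float)        # inward unit normal
    wmap = np.zeros(n)
    wmap[domain.inlet_sites] = domain.inlet_weights
    in_coeff = -6.0 * W[j_in] * wmap[s_in] * (_CF[j_in] @ n_in)

    tables = LinkTables(
        n_fluid=n, pull_src=pull_src,
        bz_dst=dst, bz_a=a, bz_b=b.astype(np.int64), bz_ca=ca, bz_cb=cb,
        in_dst=in_dst, in_a=in_a, in_site=s_in, in_coeff=in_coeff,
    )

    for o, slots in domain.outlet_link_site.items():
        dirs = domain.outlet_link_dir[o]
        if slots.size == 0:
            continue
        nvec = domain.outlet_normals[o].astype(float)
        rec = OPPOSITE[dirs]
        tables.outlets[o] = OutletTable(
            dst=rec * n + slots,
            site=slots,
            cdotn=_CF[rec] @ nvec,
            w=W[rec],
            normal=nvec,
        )
    return tables


# ------------------------------------------------------------- appliers

def apply_bouzidi_walls(f_new: np.ndarray, f_post: np.ndarray, tables: LinkTables):
    """Overwrite wall-fed slots with the two-branch Bouzidi interpolation."""
    f_new[tables.bz_dst] = (
        tables.bz_ca * f_post[tables.bz_a] + tables.bz_cb * f_post[tables.bz_b]
    )


def apply_velocity_inlet(f_new: np.ndarray, f_post: np.ndarray, rho: np.ndarray,
                         tables: LinkTables, u_lat: float):
    """Bounce-back plus the Ladd correction -2 w_i rho u.c_i / Cs^2.

    ``u_lat`` is the peak (centreline) target velocity in lattice units;
    each link scales it by its site's parabolic weight.
    """
    if abs(u_lat) / CS >= 1.0:
        raise StabilityError("target inlet velocity at or above Mach 1")
    f_new[tables.in_dst] = (
        f_post[tables.in_a] + tables.in_coeff * u_lat * rho[tables.in_site]
    )


def apply_pressure_outlet(f_new: np.ndarray, u: np.ndarray,
                          outlet: OutletTable, rho_imposed: float):
    """Phantom-site equilibrium reconstruction at one pressure outlet."""
    if rho_imposed <= 0.0:
        raise StabilityError("imposed outlet density must be positive")
    un = outlet.normal @ u[:, outlet.site]
    cu = outlet.cdotn * un
    f_new[outlet.dst] = outlet.w * rho_imposed * (
        1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * un * un
    )
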