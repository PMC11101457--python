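"""Geometry builder vs independent brute-force / ray-marching oracles."""

import math

import numpy as np
import pytest

from lbmuq.errors import GeometryError
from lbmuq.geometry import (BifurcationSpec, build_bifurcation,
                            compute_inlet_weights, compute_wall_distances,
                            cylinder_spec, extract_centreline_sites)
from lbmuq.lbm_core import C


def brute_inside(pt, spec, x0, c):
    """Independent scalar membership test (plain math, no vectorisation).

    Uses the same 1e-9 solid guard band as the builder so that site
    centres exactly on the lateral surface classify deterministically.
    """
    x, y, z = pt
    R = spec.radius
    L = spec.main_length
    r2max = R * R - 1e-9
    if x0 <= x <= x0 + L and (y - c) ** 2 + (z - c) ** 2 < r2max:
        return True
    if spec.include_branch:
        ang = math.radians(spec.branch_angle_deg)
        dx, dy = math.cos(ang), math.sin(ang)
        px, py, pz = x - (x0 + L / 2.0), y - c, z - c
        s = px * dx + py * dy
        r2 = px * px + py * py + pz * pz - s * s
        if 0.0 <= s <= spec.branch_length and r2 < r2max:
            return True
    return False


def test_fluid_count_matches_brute_force_enumeration():
    spec = BifurcationSpec(radius=4)
    dom = build_bifurcation(spec)
    count = sum(
        brute_inside((i, j, k), spec, dom.inlet_x, dom.axis_centre)
        for i in range(dom.shape[0])
        for j in range(dom.shape[1])
        for k in range(dom.shape[2])
    )
    assert dom.n_fluid == count


def test_unresolvable_lumen_rejected():
    with pytest.raises(GeometryError, match="unresolvable lumen"):
        build_bifurcation(BifurcationSpec(radius=0.5))


def test_branch_overlapping_end_cap_rejected():
    with pytest.raises(GeometryError, match="overlaps"):
        build_bifurcation(BifurcationSpec(radius=4, branch_angle_deg=5.0))


def test_straight_cylinder_layers_are_translation_invariant():
    R = 4
    dom = build_bifurcation(cylinder_spec(R, 24))
    disc = sum(1 for y in range(-R - 1, R + 2) for z in range(-R - 1, R + 2)
               if y * y + z * z < R * R)
    layers = np.bincount(dom.fluid_idx[:, 0], minlength=dom.shape[0])
    occupied = layers[layers > 0]
    assert set(occupied.tolist()) == {disc}


def test_voxelisation_is_deterministic():
    a = build_bifurcation(BifurcationSpec(radius=5))
    b = build_bifurcation(BifurcationSpec(radius=5))
    assert np.array_equal(a.site_type, b.site_type)
    assert np.array_equal(a.wall_q, b.wall_q)
    assert np.array_equal(a.main_axis_sites, b.main_axis_sites)


def test_fluid_count_scales_with_radius_squared():
    n4 = build_bifurcation(cylinder_spec(4, 24)).n_fluid
    n8 = build_bifurcation(cylinder_spec(8, 24)).n_fluid
    assert 3.6 <= n8 / n4 <= 4.4


def test_inlet_outlet_sites_on_cap_planes_and_disjoint():
    dom = build_bifurcation(BifurcationSpec(radius=5))
    assert np.all(dom.fluid_idx[dom.inlet_sites, 0] == dom.inlet_x)
    L = dom.spec.main_length
    assert np.all(dom.fluid_idx[dom.outlet_sites[1], 0] == dom.inlet_x + L)
    ch = dom.channels
    s = ch.branch_axial(dom.fluid_idx[dom.outlet_sites[0]].astype(float))
    assert np.all(s > ch.branch_length - 1.0)
    sets = [set(dom.inlet_sites.tolist()), set(dom.outlet_sites[0].tolist()),
            set(dom.outlet_sites[1].tolist())]
    assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
        and not (sets[1] & sets[2])


def test_inlet_weights_parabolic():
    dom = build_bifurcation(cylinder_spec(4, 16))
    w = compute_inlet_weights(dom)
    pos = dom.fluid_idx[dom.inlet_sites]
    c = dom.axis_centre
    centre = (pos[:, 1] == c) & (pos[:, 2] == c)
    assert w[centre] == pytest.approx(1.0)
    half = (pos[:, 1] == c + 2) & (pos[:, 2] == c)   # r = R/2
    assert w[half] == pytest.approx(0.75)
    assert np.all((w > 0.0) & (w <= 1.0))


def test_wall_q_examples():
    # integer radius: wall surface passes exactly through the neighbour centre
    dom = build_bifurcation(cylinder_spec(4, 16))
    c = dom.axis_centre
    pos = dom.fluid_idx[dom.wall_site]
    up = np.flatnonzero((pos[:, 1] == c + 3) & (pos[:, 2] == c)
                        & (dom.wall_dir == 3))      # +y link
    assert up.size > 0
    assert dom.wall_q[up] == pytest.approx(1.0, abs=1e-9)
    # half-integer radius: crossing midway along the +y link
    dom2 = build_bifurcation(cylinder_spec(4.5, 16))
    pos2 = dom2.fluid_idx[dom2.wall_site]
    c2 = dom2.axis_centre
    mid = np.flatnonzero((pos2[:, 1] == c2 + 4) & (pos2[:, 2] == c2)
                         & (dom2.wall_dir == 3))
    assert mid.size > 0
    assert dom2.wall_q[mid] == pytest.approx(0.5, abs=1e-9)


def _brute_inside_many(pts, spec, x0, c):
    """Vectorised rewrite of the scalar membership test (test-local)."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    R, L = spec.radius, spec.main_length
    r2max = R * R - 1e-9
    m = (x >= x0) & (x <= x0 + L) & ((y - c) ** 2 + (z - c) ** 2 < r2max)
    if spec.include_branch:
        ang = math.radians(spec.branch_angle_deg)
        dx, dy = math.cos(ang), math.sin(ang)
        px, py, pz = x - (x0 + L / 2.0), y - c, z - c
        s = px * dx + py * dy
        r2 = px * px + py * py + pz * pz - s * s
        m |= (s >= 0.0) & (s <= spec.branch_length) & (r2 < r2max)
    return m


def test_wall_q_against_ray_marching_oracle():
    dom = build_bifurcation(BifurcationSpec(radius=4))
    rng = np.random.default_rng(7)
    pick = rng.choice(dom.wall_site.size, size=100, replace=False)
    coarse = np.arange(0.0, 1.0 + 1e-3, 1e-3)
    for i in pick:
        p = dom.fluid_idx[dom.wall_site[i]].astype(float)
        step = C[dom.wall_dir[i]].astype(float)
        ins = _brute_inside_many(p[None, :] + coarse[:, None] * step[None, :],
                                 dom.spec, dom.inlet_x, dom.axis_centre)
        if ins.all():
            q_march = 1.0
        else:
            hi = coarse[np.argmin(ins)]
            fine = np.arange(hi - 1e-3, hi + 5e-7, 5e-7)
            fin = _brute_inside_many(p[None, :] + fine[:, None] * step[None, :],
                                     dom.spec, dom.inlet_x, dom.axis_centre)
            q_march = fine[np.argmin(fin)]
        assert abs(dom.wall_q[i] - q_march) < 1e-6


def test_wall_distances_recompute_matches_build():
    dom = build_bifurcation(BifurcationSpec(radius=4))
    _, _, q = compute_wall_distances(dom)
    assert np.allclose(q, dom.wall_q, atol=1e-12)


def test_centreline_site_counts():
    dom = build_bifurcation(cylinder_spec(5, 40))
    assert extract_centreline_sites(dom, "main").size == 41
    assert extract_centreline_sites(dom, "branch").size == 0

    dom6 = build_bifurcation(BifurcationSpec(radius=6))
    nb = extract_centreline_sites(dom6, "branch").size
    expected = math.ceil(5 * 6 * math.sqrt(2.0))
    assert abs(nb - expected) <= 1


def test_centreline_is_six_connected():
    dom = build_bifurcation(BifurcationSpec(radius=6))
    for which in ("main", "branch"):
        sites = dom.fluid_idx[extract_centreline_sites(dom, which)]
        steps = np.abs(np.diff(sites, axis=0)).sum(axis=1)
        assert np.all(steps == 1)
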