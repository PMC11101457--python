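"""Analytic oracles: Poiseuille flow, a linear-resistance bifurcation
network, Sobol test functions and a double-loop Monte-Carlo estimator.

These closed-form models make the solver and the UQ engine testable
without running (or while cross-checking) lattice simulations: the
Poiseuille solution verifies the kernel and boundary closures, the
resistor network is a drop-in fast runner producing QoI vectors of the
same shape as a real run, and the test functions carry known variance
decompositions for the Sobol machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lbm_core import PA_PER_MMHG
from .uq_engine import InputSpec


@dataclass(frozen=True)
class PoiseuilleModel:
    """Steady pressure-driven laminar flow in a cylindrical pipe.

    ``peak_velocity`` is the centreline velocity U; the parabolic profile
    is u(r) = U (1 - r^2/R^2), the flow rate pi R^2 U / 2 and the drop
    over the full length Delta p = 4 mu L U / R^2.
    """

    radius: float               # m
    length: float               # m
    mu: float = 4.0e-3          # Pa.s
    peak_velocity: float = 1e-3  # m/s

    def __post_init__(self):
        if min(self.radius, self.length, self.mu, self.peak_velocity) <= 0:
            raise ValueError("all Poiseuille parameters must be positive")

    @property
    def pressure_drop(self) -> float:
        """Total axial pressure drop in Pa."""
        return 4.0 * self.mu * self.length * self.peak_velocity / self.radius**2

    @property
    def flow_rate(self) -> float:
        """Volumetric flow rate in m^3/s (disc average of the parabola)."""
        return math.pi * self.radius**2 * self.peak_velocity / 2.0

    def profile(self, r) -> np.ndarray:
        """Axial velocity at radial positions ``r`` (m)."""
        r = np.asarray(r, dtype=float)
        return self.peak_velocity * np.maximum(0.0, 1.0 - (r / self.radius) ** 2)


def poiseuille_axis_qoi(model: PoiseuilleModel, n_sites: int) -> dict:
    """Axis-profile QoI of the analytic solution on ``n_sites`` indices.

    Speed is the constant centreline velocity; pressure falls linearly
    from the total drop at the inlet to 0 mmHg at the outlet.
    """
    frac = np.linspace(0.0, 1.0, int(n_sites))
    pressure = (1.0 - frac) * model.pressure_drop / PA_PER_MMHG
    speed = np.full(int(n_sites), model.peak_velocity)
    return {"pressure": pressure, "speed": speed}


# ------------------------------------------------ bifurcation network

@dataclass(frozen=True)
class BifurcationNetwork:
    """Three Poiseuille resistors joined at a junction (low-Re stand-in).

    Junction losses are neglected — legitimate in the creeping-flow
    regime where the boundary data, not the geometry, controls the flow
    distribution.  Arm lengths default to five radii, as in the voxel
    bifurcation.
    """

    radius: float               # m
    arm_length: float | None = None
    mu: float = 4.0e-3

    @property
    def length(self) -> float:
        return self.arm_length if self.arm_length is not None else 5.0 * self.radius

    @property
    def resistance(self) -> float:
        """Hydraulic resistance 8 mu L / (pi R^4) of one arm."""
        return 8.0 * self.mu * self.length / (math.pi * self.radius**4)

    def solve(self, inlet_peak: float, p_out0_mmhg: float, p_out1_mmhg: float):
        """Flows and node pressures for a parabolic inlet and two outlets.

        Returns (Q_in, Q0, Q1, p_junction_pa, p_inlet_pa) with outlet
        pressures converted from mmHg.
        """
        q_in = math.pi * self.radius**2 * inlet_peak / 2.0
        p0 = p_out0_mmhg * PA_PER_MMHG
        p1 = p_out1_mmhg * PA_PER_MMHG
        K = self.resistance
        pj = 0.5 * (p0 + p1 + K * q_in)
        q0 = (pj - p0) / K
        q1 = (pj - p1) / K
        p_in = pj + K * q_in
        return q_in, q0, q1, pj, p_in


def analytic_campaign_model(network: BifurcationNetwork, params: dict,
                            n_main: int, n_branch: int) -> dict:
    """QoI vectors (same schema as a lattice run) from the resistor network.

    ``params`` uses the campaign parameter names (inlet_max, outlet0_mean,
    outlet1_mean); sinusoid amplitude/period/phase are ignored — the
    stand-in is steady by construction.
    """
    u = float(params.get("inlet_max", 0.0))
    p0m = float(params.get("outlet0_mean", 0.0))
    p1m = float(params.get("outlet1_mean", 0.0))
    q_in, q0, q1, pj, p_in = network.solve(u, p0m, p1m)
    R = network.radius

    n_up = n_main // 2
    frac_up = np.linspace(0.0, 1.0, n_up + 1)
    frac_dn = np.linspace(0.0, 1.0, n_main - n_up)[1:]
    p_main = np.concatenate([
        p_in + (pj - p_in) * frac_up,
        pj + (p1m * PA_PER_MMHG - pj) * frac_dn,
    ]) / PA_PER_MMHG
    v_main = np.concatenate([
        np.full(n_up + 1, abs(_centreline_speed(q_in, R))),
        np.full(n_main - n_up - 1, abs(_centreline_speed(q1, R))),
    ])
    frac_b = np.linspace(0.0, 1.0, n_branch)
    p_branch = (pj + (p0m * PA_PER_MMHG - pj) * frac_b) / PA_PER_MMHG
    v_branch = np.full(n_branch, abs(_centreline_speed(q0, R)))
    return {
        "pressure_main": p_main, "velocity_main": v_main,
        "pressure_branch": p_branch, "velocity_branch": v_branch,
    }


def _centreline_speed(q: float, radius: float) -> float:
    """Centreline speed of a parabolic profile carrying flow ``q``."""
    return 2.0 * q / (math.pi * radius**2)


# ------------------------------------------------- Sobol test functions

def sobol_test_functions(name: str):
    """Analytic models with known variance decompositions.

    Returns ``(f, inputs, exact)`` where ``f`` maps (n, k) points to (n,)
    outputs, ``inputs`` are uniform[0, 1] specs, and ``exact`` maps
    subset tuples to Sobol indices.

    * ``linear``   : q = xi1              -> S1 = 1
    * ``additive`` : q = xi1 + xi2        -> S1 = S2 = 1/2
    * ``product``  : q = xi1 * xi2        -> S1 = S2 = 3/7, S12 = 1/7
    * ``cubic``    : a fixed random cubic in two variables (no closed
      form attached; used for PCE/collocation equivalence checks)
    """
    u = lambda nm: InputSpec(nm, 0.0, 1.0)
    if name == "linear":
        return (lambda x: x[:, 0], [u("x1")], {(0,): 1.0})
    if name == "additive":
        return (lambda x: x[:, 0] + x[:, 1], [u("x1"), u("x2")],
                {(0,): 0.5, (1,): 0.5})
    if name == "product":
        return (lambda x: x[:, 0] * x[:, 1], [u("x1"), u("x2")],
                {(0,): 3.0 / 7.0, (1,): 3.0 / 7.0, (0, 1): 1.0 / 7.0})
    if name == "cubic":
        rng = np.random.default_rng(1234)
        c = rng.normal(size=(4, 4))

        def f(x):
            v1 = np.vander(x[:, 0], 4, increasing=True)
            v2 = np.vander(x[:, 1], 4, increasing=True)
            return np.einsum("ni,ij,nj->n", v1, c, v2)

        return (f, [u("x1"), u("x2")], None)
    raise ValueError(f"unknown test function {name!r}")


def sobol_first_order_mc(f, inputs, dim: int, n_outer: int = 100_000,
                         n_inner: int = 1_000, seed: int = 0) -> float:
    """Double-loop Monte-Carlo first-order Sobol index of input ``dim``.

    S_d = Var(E[q | xi_d]) / Var(q), with the conditional expectation
    estimated by ``n_inner`` inner samples for each of ``n_outer`` outer
    values of xi_d.  Chunked to bound memory; fully seeded.
    """
    rng = np.random.default_rng(seed)
    k = len(inputs)
    lo = np.array([s.low for s in inputs])
    hi = np.array([s.high for s in inputs])
    cond_means = np.empty(n_outer)
    all_vals_sum = 0.0
    all_vals_sq = 0.0
    total = 0
    chunk = max(1, int(5e6 / n_inner))
    for a in range(0, n_outer, chunk):
        b = min(n_outer, a + chunk)
        m = b - a
        x = rng.uniform(lo, hi, size=(m, n_inner, k))
        xd = rng.uniform(lo[dim], hi[dim], size=(m, 1))
        x[:, :, dim] = xd
        vals = f(x.reshape(-1, k)).reshape(m, n_inner)
        cond_means[a:b] = vals.mean(axis=1)
        all_vals_sum += vals.sum()
        all_vals_sq += (vals**2).sum()
        total += vals.size
    var_total = all_vals_sq / total - (all_vals_sum / total) ** 2
    var_cond = cond_means.var()
    # correct the inner-loop noise bias of Var(E[q|xi_d])
    inner_var = var_total - var_cond
    var_cond_corrected = var_cond - inner_var / max(n_inner - 1, 1)
    return float(var_cond_corrected / var_total)
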