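"""Non-intrusive uncertainty quantification on tensor quadrature grids.

Inputs are independent uniform variables on printed physical ranges.
A full tensor product of (p+1)-point Gauss-Legendre rules gives
``N = (p+1)^k`` model evaluations; a polynomial chaos expansion (PCE) in
orthonormal Legendre products is fitted by spectral projection,

    c_j = sum_nodes  weight * q(node) * P_j(node),

and a stochastic-collocation surrogate (tensor Lagrange interpolation
through the same node values) is available as a cross-check — the two
agree on models of per-dimension polynomial degree <= p.

Because the basis is orthonormal, the surrogate mean is the zero-index
coefficient, the variance is the sum of the remaining squared
coefficients, and Sobol variance terms are partial sums of squared
coefficients grouped by the support of the multi-index: the fraction of
output variance attributable to each input subset, all subsets summing
to one.  Distribution summaries (mean, std, 1%/99% quantiles) and the
coefficient-of-variation ratio

    CVR = CV(q) / CV(xi)
        = mean_m sigma_qm / mu_qm  /  mean_d sigma_xid / mu_xid

complete the analysis (CVR > 1 means the model amplifies input
variability).  ``D`` is used ambiguously in the literature for both the
number of inputs and the total variance; here they are named
``input_count`` and ``total_variance``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss, legvander

from .errors import UQError

log = logging.getLogger(__name__)

#: Default seed for quantile sampling (bitwise-repeatable summaries).
DEFAULT_SEED = 20240517
_MU_FLOOR = 1e-15


@dataclass(frozen=True)
class InputSpec:
    """One uniform input variable on [low, high] in physical units."""

    name: str
    low: float
    high: float
    default: float | None = None
    integer: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise UQError(f"input {self.name}: require low < high")

    @property
    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def std(self) -> float:
        return (self.high - self.low) / np.sqrt(12.0)

    @property
    def cv(self) -> float:
        """sigma/mu of the uniform; inputs centred on zero are rejected."""
        if abs(self.mean) < _MU_FLOOR:
            raise UQError(f"input {self.name}: CV undefined for zero mean")
        return self.std / self.mean


# ------------------------------------------------------------- quadrature

@dataclass
class QuadratureGrid:
    """Full tensor Gauss-Legendre grid over the input box.

    Node enumeration is lexicographic with the *last* input fastest
    (C order of the (p+1)^k index tensor).
    """

    inputs: list
    order: int
    z1d: np.ndarray          # (p+1,) reference nodes on [-1, 1]
    w1d: np.ndarray          # (p+1,) reference weights summing to 1
    z_nodes: np.ndarray      # (N, k)
    nodes: np.ndarray        # (N, k) physical coordinates
    weights: np.ndarray      # (N,) product weights summing to 1

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def input_count(self) -> int:
        return len(self.inputs)


def tensor_grid(inputs, order: int) -> QuadratureGrid:
    """(order+1)-point Gauss-Legendre rule per input, full tensor product."""
    inputs = list(inputs)
    if order < 0:
        raise UQError("polynomial order must be >= 0")
    if not inputs:
        raise UQError("at least one input is required")
    z, w = leggauss(order + 1)
    w = w / 2.0                      # normalise to the uniform measure
    k = len(inputs)
    grids = np.meshgrid(*([z] * k), indexing="ij")
    z_nodes = np.stack([g.reshape(-1) for g in grids], axis=1)
    lo = np.array([s.low for s in inputs])
    hi = np.array([s.high for s in inputs])
    nodes = 0.5 * (lo + hi) + 0.5 * (hi - lo) * z_nodes
    wg = np.meshgrid(*([w] * k), indexing="ij")
    weights = np.prod(np.stack([g.reshape(-1) for g in wg], axis=1), axis=1)
    return QuadratureGrid(inputs=inputs, order=order, z1d=z, w1d=w,
                          z_nodes=z_nodes, nodes=nodes, weights=weights)


def _orthonormal_vander(z: np.ndarray, order: int) -> np.ndarray:
    """Legendre Vandermonde with columns normalised under uniform[-1, 1]."""
    v = legvander(z, order)
    return v * np.sqrt(2.0 * np.arange(order + 1) + 1.0)


def _multi_indices(k: int, order: int) -> np.ndarray:
    return np.array(list(itertools.product(range(order + 1), repeat=k)),
                    dtype=np.int64)


# ------------------------------------------------------------------ PCE

@dataclass
class PCESurrogate:
    """Orthonormal-Legendre polynomial chaos expansion of a QoI vector."""

    inputs: list
    order: int
    multi_indices: np.ndarray     # (T, k)
    coeffs: np.ndarray            # (T, M)
    node_residual: float = 0.0

    @property
    def input_count(self) -> int:
        return len(self.inputs)

    @property
    def mean(self) -> np.ndarray:
        return self.coeffs[0].copy()

    @property
    def variance(self) -> np.ndarray:
        return (self.coeffs[1:] ** 2).sum(axis=0)

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def _to_reference(self, xi: np.ndarray) -> np.ndarray:
        lo = np.array([s.low for s in self.inputs])
        hi = np.array([s.high for s in self.inputs])
        return (2.0 * xi - (lo + hi)) / (hi - lo)

    def __call__(self, xi) -> np.ndarray:
        """Evaluate at physical points ``xi`` of shape (n, k) -> (n, M)."""
        xi = np.atleast_2d(np.asarray(xi, dtype=float))
        z = self._to_reference(xi)
        n, T = xi.shape[0], self.multi_indices.shape[0]
        out = np.empty((n, self.coeffs.shape[1]))
        chunk = max(1, int(2**22 / max(T, 1)))
        vander = [_orthonormal_vander(z[:, d], self.order)
                  for d in range(self.input_count)]
        for a in range(0, n, chunk):
            b = min(n, a + chunk)
            phi = np.ones((b - a, T))
            for d in range(self.input_count):
                phi *= vander[d][a:b][:, self.multi_indices[:, d]]
            out[a:b] = phi @ self.coeffs
        return out


def fit_pce(grid: QuadratureGrid, outputs) -> PCESurrogate:
    """Spectral projection of node outputs onto the orthonormal basis.

    ``outputs`` has shape (N,) or (N, M) with one row per grid node, in
    grid enumeration order.
    """
    y = np.asarray(outputs, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != grid.n_nodes:
        raise UQError(
            f"outputs rows ({y.shape[0]}) != grid nodes ({grid.n_nodes})"
        )
    if not np.all(np.isfinite(y)):
        node = int(np.argwhere(~np.isfinite(y))[0][0])
        raise UQError(f"non-finite model output at node {node}: "
                      f"{grid.nodes[node].tolist()}")
    k, p = grid.input_count, grid.order
    mi = _multi_indices(k, p)
    phi = np.ones((grid.n_nodes, mi.shape[0]))
    for d in range(k):
        vd = _orthonormal_vander(grid.z_nodes[:, d], p)
        phi *= vd[:, mi[:, d]]
    coeffs = phi.T @ (grid.weights[:, None] * y)
    resid = float(np.max(np.abs(phi @ coeffs - y))) if y.size else 0.0
    return PCESurrogate(inputs=grid.inputs, order=p, multi_indices=mi,
                        coeffs=coeffs, node_residual=resid)


# -------------------------------------------------------- collocation

@dataclass
class LagrangeSurrogate:
    """Stochastic-collocation surrogate: tensor Lagrange interpolation."""

    inputs: list
    order: int
    z1d: np.ndarray
    node_values: np.ndarray        # (N, M) in grid enumeration order

    def __call__(self, xi) -> np.ndarray:
        xi = np.atleast_2d(np.asarray(xi, dtype=float))
        lo = np.array([s.low for s in self.inputs])
        hi = np.array([s.high for s in self.inputs])
        z = (2.0 * xi - (lo + hi)) / (hi - lo)
        p1 = self.order + 1
        k = len(self.inputs)
        # barycentric weights of the 1D node set
        diff = self.z1d[:, None] - self.z1d[None, :]
        np.fill_diagonal(diff, 1.0)
        bw = 1.0 / diff.prod(axis=1)
        basis = []
        for d in range(k):
            dz = z[:, d][:, None] - self.z1d[None, :]
            exact = np.isclose(dz, 0.0, atol=1e-14)
            safe = np.where(exact, 1.0, dz)
            terms = bw[None, :] / safe
            bd = terms / terms.sum(axis=1, keepdims=True)
            hit = exact.any(axis=1)
            bd[hit] = exact[hit].astype(float)
            basis.append(bd)
        idx = _multi_indices(k, self.order)      # node enumeration = basis index
        phi = np.ones((z.shape[0], idx.shape[0]))
        for d in range(k):
            phi *= basis[d][:, idx[:, d]]
        return phi @ self.node_values


def collocation_surrogate(grid: QuadratureGrid, outputs) -> LagrangeSurrogate:
    """Lagrange tensor interpolant through the model outputs at the nodes."""
    y = np.asarray(outputs, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != grid.n_nodes:
        raise UQError("outputs rows do not match grid nodes")
    return LagrangeSurrogate(inputs=grid.inputs, order=grid.order,
                             z1d=grid.z1d, node_values=y)


# ------------------------------------------------------------- Sobol

@dataclass
class SobolResult:
    """Variance decomposition of a PCE surrogate over the subset lattice."""

    input_names: list
    first_order: np.ndarray        # (k, M)
    higher_orders: np.ndarray      # (M,) lumped 1 - sum first-order
    by_subset: dict                # tuple(dims) -> (M,) Sobol index
    total_variance: np.ndarray     # (M,)
    degenerate: np.ndarray         # (M,) bool: zero-variance components


def sobol_indices(surrogate: PCESurrogate) -> SobolResult:
    """Sobol indices from squared PCE coefficients.

    D_u sums c_j^2 over multi-indices supported exactly on subset u;
    S_u = D_u / D with D the total variance.  Degenerate (constant)
    components report all-zero indices and are flagged.
    """
    mi = surrogate.multi_indices
    c2 = surrogate.coeffs**2
    M = c2.shape[1]
    D = c2[1:].sum(axis=0)
    degenerate = D <= 0.0
    Dsafe = np.where(degenerate, 1.0, D)
    support = [tuple(np.flatnonzero(row)) for row in mi]
    by_subset: dict = {}
    for j, sup in enumerate(support):
        if not sup:
            continue
        acc = by_subset.setdefault(sup, np.zeros(M))
        acc += c2[j]
    for sup in by_subset:
        by_subset[sup] = np.where(degenerate, 0.0, by_subset[sup] / Dsafe)
    k = surrogate.input_count
    first = np.zeros((k, M))
    for d in range(k):
        if (d,) in by_subset:
            first[d] = by_subset[(d,)]
    higher = np.where(degenerate, 0.0, 1.0 - first.sum(axis=0))
    return SobolResult(
        input_names=[s.name for s in surrogate.inputs],
        first_order=first, higher_orders=higher, by_subset=by_subset,
        total_variance=D, degenerate=degenerate,
    )


# ----------------------------------------------------------- summaries

@dataclass
class DistributionSummary:
    """Per-component mean, std and 1%/99% quantiles of the output."""

    mean: np.ndarray
    std: np.ndarray
    q01: np.ndarray
    q99: np.ndarray


def summarize_distribution(surrogate: PCESurrogate, n_samples: int = 100_000,
                           seed: int = DEFAULT_SEED) -> DistributionSummary:
    """Analytic mean/std from the PCE; quantiles by seeded surrogate sampling."""
    rng = np.random.default_rng(seed)
    lo = np.array([s.low for s in surrogate.inputs])
    hi = np.array([s.high for s in surrogate.inputs])
    xi = rng.uniform(lo, hi, size=(int(n_samples), len(surrogate.inputs)))
    samples = surrogate(xi)
    q01, q99 = np.quantile(samples, [0.01, 0.99], axis=0)
    return DistributionSummary(mean=surrogate.mean, std=surrogate.std,
                               q01=q01, q99=q99)


# ------------------------------------------------------------ CV / CVR

def input_cv(inputs) -> float:
    """Mean sigma/mu over the input variables (closed form for uniforms)."""
    inputs = list(inputs)
    if not inputs:
        raise UQError("no inputs")
    return float(np.mean([s.cv for s in inputs]))


def output_cv(mean: np.ndarray, std: np.ndarray) -> float:
    """Mean sigma/mu over QoI components; near-zero means are excluded.

    sigma/mu diverges as mu -> 0, so components with |mu| below 1e-15
    are dropped from the average (the count is logged).
    """
    mean = np.asarray(mean, dtype=float).reshape(-1)
    std = np.asarray(std, dtype=float).reshape(-1)
    keep = np.abs(mean) >= _MU_FLOOR
    dropped = int((~keep).sum())
    if dropped:
        log.info("output_cv: excluded %d near-zero-mean components", dropped)
    if not np.any(keep):
        raise UQError("all QoI components have (near) zero mean; CV undefined")
    return float(np.mean(std[keep] / np.abs(mean[keep])))


def cvr(cv_q: float, inputs) -> float:
    """Coefficient-of-variation ratio CV(q)/CV(xi)."""
    return cv_q / input_cv(inputs)
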