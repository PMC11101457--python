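"""Quadrature, PCE projection, collocation, Sobol indices, CV/CVR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lbmuq.errors import UQError
from lbmuq.reference_models import sobol_first_order_mc, sobol_test_functions
from lbmuq.uq_engine import (InputSpec, collocation_surrogate, cvr, fit_pce,
                             input_cv, output_cv, sobol_indices,
                             summarize_distribution, tensor_grid)


def unit_inputs(k):
    return [InputSpec(f"x{i}", 0.0, 1.0) for i in range(k)]


# ------------------------------------------------------------ quadrature

@pytest.mark.parametrize("k,p,n", [(4, 3, 256), (1, 0, 1), (3, 3, 64)])
def test_tensor_grid_node_counts(k, p, n):
    g = tensor_grid(unit_inputs(k), p)
    assert g.n_nodes == n


def test_single_point_rule_sits_at_the_mean():
    g = tensor_grid([InputSpec("a", 2.0, 6.0)], 0)
    assert g.nodes[0, 0] == pytest.approx(4.0)
    assert g.w1d.sum() == pytest.approx(1.0)


def test_grid_weights_sum_to_one():
    g = tensor_grid(unit_inputs(3), 2)
    assert g.weights.sum() == pytest.approx(1.0, abs=1e-13)


def test_bad_inputs_rejected():
    with pytest.raises(UQError):
        InputSpec("a", 1.0, 1.0)
    with pytest.raises(UQError):
        tensor_grid([], 2)


# ------------------------------------------------------------------ PCE

def test_pce_constant_model():
    g = tensor_grid(unit_inputs(2), 2)
    pce = fit_pce(g, np.full(g.n_nodes, 5.0))
    assert pce.coeffs[0, 0] == pytest.approx(5.0, abs=1e-13)
    assert np.max(np.abs(pce.coeffs[1:])) < 1e-12


def test_pce_identity_moments():
    g = tensor_grid(unit_inputs(1), 1)
    pce = fit_pce(g, g.nodes[:, 0])
    assert pce.mean[0] == pytest.approx(0.5, abs=1e-12)
    assert pce.variance[0] == pytest.approx(1.0 / 12.0, abs=1e-12)


def test_pce_reproduces_polynomial_models_exactly():
    g = tensor_grid(unit_inputs(2), 3)
    y = g.nodes[:, 0] + g.nodes[:, 1] ** 2
    pce = fit_pce(g, y)
    rng = np.random.default_rng(42)
    pts = rng.uniform(0.0, 1.0, size=(50, 2))
    assert np.max(np.abs(pce(pts)[:, 0] - (pts[:, 0] + pts[:, 1] ** 2))) < 1e-10


def test_pce_input_validation():
    g = tensor_grid(unit_inputs(2), 1)
    with pytest.raises(UQError, match="nodes"):
        fit_pce(g, np.zeros(3))
    bad = np.zeros(g.n_nodes)
    bad[2] = np.nan
    with pytest.raises(UQError, match="node 2"):
        fit_pce(g, bad)


def test_raising_order_leaves_converged_statistics_unchanged():
    """Once p exceeds the model's degree, nothing moves (order check)."""
    f, inputs, _ = sobol_test_functions("product")
    stats = []
    for p in (2, 4, 5):
        g = tensor_grid(inputs, p)
        pce = fit_pce(g, f(g.nodes))
        sr = sobol_indices(pce)
        stats.append((pce.mean[0], pce.variance[0],
                      sr.first_order[0, 0], sr.first_order[1, 0]))
    for a, b in zip(stats[:-1], stats[1:]):
        assert np.allclose(a, b, atol=1e-10)


# ----------------------------------------------------------- collocation

def test_collocation_matches_pce_on_polynomials():
    f, inputs, _ = sobol_test_functions("cubic")
    g = tensor_grid(inputs, 3)
    y = f(g.nodes)
    pce = fit_pce(g, y)
    lag = collocation_surrogate(g, y)
    rng = np.random.default_rng(1)
    pts = rng.uniform(0.0, 1.0, size=(20, 2))
    assert np.max(np.abs(pce(pts) - lag(pts))) < 1e-10
    # exact at the nodes themselves
    assert np.max(np.abs(lag(g.nodes)[:, 0] - y)) < 1e-12


def test_collocation_constant_and_linear_exact():
    g = tensor_grid(unit_inputs(2), 1)
    lag = collocation_surrogate(g, np.full(g.n_nodes, 3.3))
    assert np.allclose(lag(np.array([[0.2, 0.9]])), 3.3, atol=1e-13)
    y = 2.0 * g.nodes[:, 0] - g.nodes[:, 1]
    lag2 = collocation_surrogate(g, y)
    pts = np.array([[0.1, 0.4], [0.8, 0.2]])
    assert np.allclose(lag2(pts)[:, 0], 2 * pts[:, 0] - pts[:, 1], atol=1e-13)


# ---------------------------------------------------------------- Sobol

@pytest.mark.parametrize("name", ["linear", "additive", "product"])
def test_sobol_closed_forms(name):
    f, inputs, exact = sobol_test_functions(name)
    g = tensor_grid(inputs, 3)
    sr = sobol_indices(fit_pce(g, f(g.nodes)))
    for subset, val in exact.items():
        if len(subset) == 1:
            assert sr.first_order[subset[0], 0] == pytest.approx(val, abs=1e-10)
        else:
            assert sr.by_subset[subset][0] == pytest.approx(val, abs=1e-10)


@given(st.integers(0, 10_000))
def test_sobol_indices_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    g = tensor_grid(unit_inputs(3), 2)
    y = rng.normal(size=g.n_nodes)
    sr = sobol_indices(fit_pce(g, y))
    total = sum(v[0] for v in sr.by_subset.values())
    assert total == pytest.approx(1.0, abs=1e-10)
    assert all(-1e-10 <= v[0] <= 1 + 1e-10 for v in sr.by_subset.values())


def test_sobol_degenerate_constant_output():
    g = tensor_grid(unit_inputs(2), 1)
    sr = sobol_indices(fit_pce(g, np.full(g.n_nodes, 2.0)))
    assert sr.degenerate.all()
    assert np.all(sr.first_order == 0.0)
    assert np.all(sr.higher_orders == 0.0)


def test_sobol_agrees_with_double_loop_monte_carlo():
    for name in ("additive", "product"):
        f, inputs, exact = sobol_test_functions(name)
        g = tensor_grid(inputs, 3)
        sr = sobol_indices(fit_pce(g, f(g.nodes)))
        for d in range(len(inputs)):
            mc = sobol_first_order_mc(f, inputs, d, n_outer=20_000,
                                      n_inner=400, seed=100 + d)
            assert abs(mc - sr.first_order[d, 0]) < 0.02


# ------------------------------------------------------------ summaries

def test_summary_of_identity_has_uniform_quantiles():
    g = tensor_grid(unit_inputs(1), 2)
    pce = fit_pce(g, g.nodes[:, 0])
    s = summarize_distribution(pce, seed=7)
    assert s.q01[0] == pytest.approx(0.01, abs=0.005)
    assert s.q99[0] == pytest.approx(0.99, abs=0.005)
    assert s.q01[0] <= s.mean[0] <= s.q99[0]
    s2 = summarize_distribution(pce, seed=7)
    assert np.array_equal(s.q01, s2.q01)        # bitwise repeatable


def test_summary_of_constant_model_collapses():
    g = tensor_grid(unit_inputs(2), 1)
    s = summarize_distribution(fit_pce(g, np.full(g.n_nodes, 1.5)), seed=1)
    assert s.mean[0] == pytest.approx(1.5, abs=1e-12)
    assert s.std[0] == pytest.approx(0.0, abs=1e-12)
    assert s.q01[0] == pytest.approx(s.q99[0], abs=1e-12)


# ------------------------------------------------------------- CV / CVR

def test_input_cv_closed_forms():
    assert input_cv([InputSpec("a", 0.0, 7.0)]) == pytest.approx(
        2.0 / np.sqrt(12.0), abs=1e-12)
    algo = [InputSpec("voxel_size", 5e-5, 1.5e-4),
            InputSpec("step_length", 6e-5, 1.2e-4),
            InputSpec("steps", 2500, 5000)]
    assert input_cv(algo) == pytest.approx(0.2245, abs=5e-5)


def test_input_cv_rejects_zero_mean():
    with pytest.raises(UQError):
        InputSpec("sym", -1.0, 1.0).cv


def test_output_cv_excludes_near_zero_means():
    mean = np.array([1.0, 0.0, 2.0])
    std = np.array([0.1, 5.0, 0.4])
    assert output_cv(mean, std) == pytest.approx(0.15)
    with pytest.raises(UQError):
        output_cv(np.zeros(3), np.ones(3))


def test_cvr_identity_and_linearity():
    inputs = [InputSpec("a", 1.0, 3.0)]
    cv_in = input_cv(inputs)
    assert cvr(cv_in, inputs) == pytest.approx(1.0)
    assert cvr(2 * cv_in, inputs) == pytest.approx(2.0)


def test_cvr_scale_invariance_for_linear_model():
    """q = c * xi with one input: CV passes through unchanged."""
    inputs = [InputSpec("a", 1.0, 3.0)]
    g = tensor_grid(inputs, 2)
    for c in (0.5, 7.0):
        pce = fit_pce(g, c * g.nodes[:, 0])
        cv_q = output_cv(pce.mean, pce.std)
        assert cvr(cv_q, inputs) == pytest.approx(1.0, rel=1e-10)
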