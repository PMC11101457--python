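"""Campaign orchestration: presets, node execution, caching, UQ analysis.

A campaign fixes a voxel geometry and a set of run parameters, declares
which parameters are uncertain (uniform ranges in physical units),
executes the solver at every node of the tensor quadrature grid, and
feeds the assembled QoI matrices to the UQ engine (PCE, Sobol indices,
distribution summaries, CV/CVR).

Parameter names follow the conventions of templated vascular LBM runs:
``voxel_size`` (dx, m), ``step_length`` (dt, s), ``steps``,
``inlet_max`` (peak inlet velocity, m/s) and, per sinusoidal pressure
outlet, ``outletN_mean``/``_amplitude`` (mmHg), ``_period`` (s),
``_phase`` (rad).  Outlet 0 is the side branch and outlet 1 the main
channel — a documented convention of this package, not a fact of the
labels' provenance.

Within one campaign the lattice geometry is fixed; ``voxel_size`` and
``step_length`` act through the unit system (relaxation time, velocity
and pressure scales, implied physical size), which is how a fixed
pre-processed lattice experiences discretisation uncertainty.  ``steps``
is an integer input: quadrature nodes are rounded to the nearest whole
number of steps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boundaries import ConstantInlet, SinusoidalPressure, TransientInlet
from .errors import CampaignError, SimulationDiverged
from .geometry import BifurcationSpec, build_bifurcation
from .lbm_core import UnitSystem
from .qoi import PlaneRecorder, PlaneSpec, extract_axis_profile
from .reference_models import BifurcationNetwork, analytic_campaign_model
from .solver import Simulation
from .uq_engine import (DEFAULT_SEED, DistributionSummary, InputSpec,
                        PCESurrogate, SobolResult, cvr, fit_pce, input_cv,
                        output_cv, sobol_indices, summarize_distribution,
                        tensor_grid)

log = logging.getLogger(__name__)

NU_BLOOD = 4.0e-6      # m^2/s, kinematic viscosity of the model fluid

DEFAULTS = {
    "voxel_size": 5.0e-5,
    "step_length": 6.0e-5,
    "steps": 5000,
    "inlet_max": 0.001,
    "outlet0_mean": 0.0, "outlet0_amplitude": 0.0,
    "outlet0_period": 1.0, "outlet0_phase": 0.0,
    "outlet1_mean": 0.0, "outlet1_amplitude": 0.0,
    "outlet1_period": 1.0, "outlet1_phase": 0.0,
}

#: Personalised-forearm run constants (transient campaign emulation).
FOREARM_STEPS = 325_000
FOREARM_DT = 5.0e-6
FOREARM_DX = 5.0e-5

PRESET_NAMES = ("algorithmic", "algorithmic_converged",
                "BC1", "BC2", "BC3", "BC4", "transient_demo")


def simulated_time(steps: int, dt: float) -> float:
    """Physical time covered by a run (s)."""
    return steps * dt


def count_boundary_parameters(inlets: int, outlets: int,
                              mode: str = "velocity_inlet") -> int:
    """Size of the tunable parameter space of one run configuration.

    Three algorithmic parameters (dx, dt, steps) plus four sinusoid
    parameters per pressure boundary; a velocity inlet contributes one
    (its maximum velocity): 3 + 4(I+O) in all-pressure mode, 3 + I + 4O
    with velocity inlets.
    """
    if inlets <= 0:
        raise CampaignError("at least one driving inlet is required")
    if mode == "pressure":
        return 3 + 4 * (inlets + outlets)
    if mode == "velocity_inlet":
        return 3 + inlets + 4 * outlets
    raise CampaignError(f"unknown boundary mode {mode!r}")


@dataclass
class CampaignConfig:
    """Everything needed to run and analyse one campaign."""

    name: str
    radius: float                      # lattice units
    inputs: list
    fixed: dict = field(default_factory=dict)
    order: int = 3
    include_branch: bool = True
    runner: str = "lbm"                # "lbm" | "analytic"
    transient: bool = False
    ramp_steps: int = 0                # inlet half-cosine ramp (steady runs)
    n_plane_samples: int = 32
    seed: int = DEFAULT_SEED
    outdir: Path | None = None

    def __post_init__(self):
        names = [s.name for s in self.inputs]
        if len(set(names)) != len(names):
            raise CampaignError("duplicate input names")
        clash = set(names) & set(self.fixed)
        if clash:
            raise CampaignError(f"inputs also listed as fixed: {sorted(clash)}")
        unknown = (set(names) | set(self.fixed)) - set(DEFAULTS)
        if unknown:
            raise CampaignError(f"unknown parameter names: {sorted(unknown)}")
        if self.order < 1:
            raise CampaignError("Sobol analysis requires order >= 1")

    def node_params(self, values) -> dict:
        p = dict(DEFAULTS)
        p.update(self.fixed)
        p.update({s.name: float(v) for s, v in zip(self.inputs, values)})
        p["steps"] = int(round(p["steps"]))
        return p


@dataclass
class QoIAnalysis:
    """UQ outputs for one QoI vector."""

    name: str
    surrogate: PCESurrogate
    sobol: SobolResult
    summary: DistributionSummary


@dataclass
class UQResult:
    """Bundle returned by :func:`run_campaign`."""

    config: CampaignConfig
    qois: dict
    cv_q: float
    cv_xi: float
    cvr: float
    n_nodes: int
    n_executed: int
    tau_range: tuple
    max_mach: float
    max_reynolds: float


# ------------------------------------------------------------- runners

def _outlet_programs(domain, params) -> dict:
    programs = {}
    for o in domain.outlet_normals:
        programs[o] = SinusoidalPressure(
            mean=params[f"outlet{o}_mean"],
            amplitude=params[f"outlet{o}_amplitude"],
            period=params[f"outlet{o}_period"],
            phase=params[f"outlet{o}_phase"],
        )
    return programs


def _lbm_node(config: CampaignConfig, domain, params: dict) -> tuple[dict, dict]:
    """Run the solver at one parameter point; return (qois, run metadata)."""
    units = UnitSystem(dx=params["voxel_size"], dt=params["step_length"])
    steps = params["steps"]
    dt = params["step_length"]
    if config.transient:
        total = steps * dt
        inlet = TransientInlet(
            base=DEFAULTS["inlet_max"], peak=params.get("inlet_max", 0.005),
            ramp_duration=0.5 * total, pulse_start=0.5 * total,
            pulse_duration=0.45 * total,
        )
    else:
        inlet = ConstantInlet(params["inlet_max"],
                              ramp_duration=config.ramp_steps * dt)
    sim = Simulation(domain, units, inlet=inlet,
                     outlets=_outlet_programs(domain, params))
    try:
        if config.transient:
            recorders = _plane_recorders(domain, units)
            t0, t1 = 0.5 * steps, 0.95 * steps
            sample_at = sorted({int(round(s)) for s in
                               np.linspace(t0, t1, config.n_plane_samples)})

            def sampler(s, t):
                for rec in recorders.values():
                    rec(s, t)

            sim.run(steps, sample_at=sample_at, sampler=sampler)
            qois = {}
            for label, rec in recorders.items():
                qois[f"plane_{label}_mean"] = np.array(rec.series.mean_speed)
                qois[f"plane_{label}_max"] = np.array(rec.series.max_speed)
        else:
            sim.run(steps)
            qois = {}
            for branch in ("main", "branch"):
                prof = extract_axis_profile(sim.state, domain, units, branch)
                if prof.index.size:
                    qois[f"pressure_{branch}"] = prof.pressure
                    qois[f"velocity_{branch}"] = prof.speed
    except SimulationDiverged as exc:
        raise CampaignError(
            f"node diverged ({exc}); parameters: {json.dumps(params)}"
        ) from exc
    meta = {"tau": sim.tau, "max_mach": sim.max_mach, "steps": steps}
    return qois, meta


def _plane_recorders(domain, units) -> dict:
    """Mid-arm analysis planes for the transient (forearm-style) campaign."""
    ch = domain.channels
    x_mid_dn = ch.x0 + 0.75 * ch.length
    planes = {
        "main": PlaneSpec(point=(x_mid_dn, ch.centre, ch.centre),
                          normal=(1.0, 0.0, 0.0), radius=ch.radius + 1.0),
    }
    if ch.has_branch:
        pt = ch.p0 + 0.5 * ch.branch_length * ch.d
        planes["branch"] = PlaneSpec(point=tuple(pt), normal=tuple(ch.d),
                                     radius=ch.radius + 1.0)
    return {k: PlaneRecorder(domain, units, v) for k, v in planes.items()}


def _analytic_node(config: CampaignConfig, domain, params: dict):
    """Closed-form resistor-network stand-in with lattice-matched shapes."""
    units = UnitSystem(dx=params["voxel_size"], dt=params["step_length"])
    network = BifurcationNetwork(radius=config.radius * units.dx)
    qois = analytic_campaign_model(
        network, params,
        n_main=domain.main_axis_sites.size,
        n_branch=domain.branch_axis_sites.size,
    )
    qois = {k: v for k, v in qois.items() if v.size}
    return qois, {"tau": units.tau, "max_mach": 0.0, "steps": params["steps"]}


# ------------------------------------------------------------- caching

def _run_hash(config: CampaignConfig, params: dict) -> str:
    payload = {
        "radius": config.radius,
        "include_branch": config.include_branch,
        "runner": config.runner,
        "transient": config.transient,
        "ramp_steps": config.ramp_steps,
        "n_plane_samples": config.n_plane_samples if config.transient else None,
        "params": {k: repr(v) for k, v in sorted(params.items())},
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _save_run(run_dir: Path, params: dict, qois: dict, meta: dict):
    run_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(qois):
        v = qois[name]
        rows.append(pd.DataFrame(
            {"qoi": name, "idx": np.arange(v.size), "value": v}))
    pd.concat(rows, ignore_index=True).to_csv(
        run_dir / "qoi.csv", index=False, float_format="%.17g")
    (run_dir / "run.json").write_text(
        json.dumps({"params": params, "meta": meta}, indent=2, sort_keys=True))


def _load_run(run_dir: Path):
    path = run_dir / "qoi.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path, float_precision="round_trip")
    qois = {name: g.sort_values("idx")["value"].to_numpy()
            for name, g in df.groupby("qoi")}
    meta = json.loads((run_dir / "run.json").read_text())["meta"]
    return qois, meta


# ------------------------------------------------------------ campaign

def run_campaign(config: CampaignConfig) -> UQResult:
    """Execute the full grid, analyse, and (optionally) persist outputs.

    Completed nodes found in the cache directory are reused, so an
    interrupted campaign resumes without re-running finished work.
    Any diverged node aborts the whole campaign with its parameters.
    """
    grid = tensor_grid(config.inputs, config.order)
    spec = BifurcationSpec(radius=config.radius,
                           include_branch=config.include_branch)
    domain = build_bifurcation(spec)
    runner = {"lbm": _lbm_node, "analytic": _analytic_node}.get(config.runner)
    if runner is None:
        raise CampaignError(f"unknown runner {config.runner!r}")

    outputs: dict[str, list] = {}
    metas = []
    executed = 0
    runs_root = Path(config.outdir) / "runs" if config.outdir else None
    for values in grid.nodes:
        params = config.node_params(values)
        cached = None
        run_dir = None
        if runs_root is not None:
            run_dir = runs_root / _run_hash(config, params)
            cached = _load_run(run_dir)
        if cached is None:
            qois, meta = runner(config, domain, params)
            executed += 1
            if run_dir is not None:
                _save_run(run_dir, params, qois, meta)
        else:
            qois, meta = cached
        metas.append(meta)
        for name, vec in qois.items():
            outputs.setdefault(name, []).append(np.asarray(vec, dtype=float))

    qoi_results = {}
    means, stds = [], []
    for name in sorted(outputs):
        Y = np.stack(outputs[name])
        pce = fit_pce(grid, Y)
        analysis = QoIAnalysis(
            name=name, surrogate=pce, sobol=sobol_indices(pce),
            summary=summarize_distribution(pce, seed=config.seed),
        )
        qoi_results[name] = analysis
        means.append(analysis.summary.mean)
        stds.append(analysis.summary.std)

    cv_q = output_cv(np.concatenate(means), np.concatenate(stds))
    cv_xi = input_cv(config.inputs)
    taus = [m["tau"] for m in metas]
    result = UQResult(
        config=config, qois=qoi_results,
        cv_q=cv_q, cv_xi=cv_xi, cvr=cv_q / cv_xi,
        n_nodes=grid.n_nodes, n_executed=executed,
        tau_range=(min(taus), max(taus)),
        max_mach=max(m["max_mach"] for m in metas),
        max_reynolds=max_reynolds(config),
    )
    if config.outdir:
        write_result(result, Path(config.outdir))
    return result


def write_result(result: UQResult, outdir: Path):
    """Persist per-QoI CSV tables and a campaign summary JSON."""
    analysis_dir = outdir / "analysis"
    analysis_dir.mkdir(parents=True, exist_ok=True)
    for name, qa in result.qois.items():
        cols = {
            "index": np.arange(qa.summary.mean.size),
            "mean": qa.summary.mean, "std": qa.summary.std,
            "q01": qa.summary.q01, "q99": qa.summary.q99,
        }
        for d, iname in enumerate(qa.sobol.input_names):
            cols[f"sobol_{iname}"] = qa.sobol.first_order[d]
        cols["higher_orders"] = qa.sobol.higher_orders
        pd.DataFrame(cols).to_csv(analysis_dir / f"{name}.csv", index=False,
                                  float_format="%.17g")
    summary = {
        "campaign": result.config.name,
        "n_nodes": result.n_nodes,
        "n_executed": result.n_executed,
        "cv_q": result.cv_q, "cv_xi": result.cv_xi, "cvr": result.cvr,
        "tau_range": list(result.tau_range),
        "max_mach": result.max_mach,
        "max_reynolds": result.max_reynolds,
    }
    (analysis_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))


# ------------------------------------------------------------- presets

def _upper(config: CampaignConfig, name: str) -> float:
    for s in config.inputs:
        if s.name == name:
            return s.high
    return float(config.fixed.get(name, DEFAULTS[name]))


def max_reynolds(config: CampaignConfig) -> float:
    """Largest Reynolds number over the campaign's input hull.

    Re = U_max * 2 R_phys / nu with R_phys the lattice radius at the
    largest voxel size in play.
    """
    u = _upper(config, "inlet_max")
    dx = _upper(config, "voxel_size")
    return u * 2.0 * config.radius * dx / NU_BLOOD


def preset(name: str, scale: float = 1.0, order: int = 3,
           fine: bool = False, runner: str = "lbm",
           seed: int = DEFAULT_SEED, outdir=None) -> CampaignConfig:
    """Campaign presets carrying the reference input ranges.

    ``scale`` shrinks the lattice radius and the step counts
    proportionally for desk-scale execution; the physical input ranges
    are never altered.  ``fine`` switches to the doubled-resolution
    variant (radius 40, halved dx, quartered dt, 4x steps).
    """
    if name not in PRESET_NAMES:
        raise CampaignError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if not 0.0 < scale <= 1.0:
        raise CampaignError("scale must lie in (0, 1]")
    radius = max(3, int(round((40 if fine else 20) * scale)))

    def scaled_steps(n: int) -> int:
        return max(1, int(round(n * scale)))

    kw = dict(order=order, runner=runner, seed=seed, outdir=outdir)

    if name in ("algorithmic", "algorithmic_converged"):
        mult = 10 if name == "algorithmic_converged" else 1
        base_steps = (10000, 20000) if fine else (2500, 5000)
        dxr = (2.5e-5, 7.5e-5) if fine else (5e-5, 1.5e-4)
        dtr = (1.5e-5, 3.0e-5) if fine else (6e-5, 1.2e-4)
        inputs = [
            InputSpec("voxel_size", *dxr),
            InputSpec("step_length", *dtr),
            InputSpec("steps", scaled_steps(base_steps[0] * mult),
                      scaled_steps(base_steps[1] * mult), integer=True),
        ]
        fixed = {"inlet_max": 0.001}
        return CampaignConfig(name=name, radius=radius, inputs=inputs,
                              fixed=fixed, **kw)

    fixed_alg = {
        "voxel_size": 2.5e-5 if fine else 5e-5,
        "step_length": 1.5e-5 if fine else 6e-5,
        "steps": scaled_steps(20000 if fine else 5000),
    }
    vel = ("inlet_max", 0.0, 0.005)
    pr = (0.0, 0.00025)

    if name in ("BC1", "BC2"):
        o = 0 if name == "BC1" else 1
        inputs = [
            InputSpec(*vel),
            InputSpec(f"outlet{o}_mean", *pr),
            InputSpec(f"outlet{o}_amplitude", *pr),
            InputSpec(f"outlet{o}_period", 1.0, 2.0),
            InputSpec(f"outlet{o}_phase", 0.0, 0.05),
        ]
        return CampaignConfig(name=name, radius=radius, inputs=inputs,
                              fixed=fixed_alg, **kw)
    if name == "BC3":
        inputs = [
            InputSpec("outlet0_mean", *pr),
            InputSpec("outlet0_amplitude", *pr),
            InputSpec("outlet0_phase", 0.0, 0.05),
            InputSpec("outlet1_mean", *pr),
            InputSpec("outlet1_amplitude", *pr),
            InputSpec("outlet1_phase", 0.0, 0.05),
        ]
        return CampaignConfig(name=name, radius=radius, inputs=inputs,
                              fixed=dict(fixed_alg, inlet_max=0.001), **kw)
    if name == "BC4":
        inputs = [
            InputSpec(*vel),
            InputSpec("outlet0_mean", *pr),
            InputSpec("outlet0_amplitude", *pr),
            InputSpec("outlet1_mean", *pr),
            InputSpec("outlet1_amplitude", *pr),
        ]
        return CampaignConfig(name=name, radius=radius, inputs=inputs,
                              fixed=fixed_alg, **kw)

    # transient_demo: forearm-style pulsatile study on the bifurcation
    inputs = [
        InputSpec("outlet0_mean", 0.0, 0.2),
        InputSpec("outlet0_amplitude", 0.0, 0.2),
        InputSpec("outlet1_mean", 0.0, 0.2),
        InputSpec("outlet1_amplitude", 0.0, 0.2),
    ]
    fixed = {"voxel_size": FOREARM_DX, "step_length": FOREARM_DT,
             "steps": scaled_steps(FOREARM_STEPS), "inlet_max": 0.005}
    return CampaignConfig(name=name, radius=radius, inputs=inputs,
                          fixed=fixed, transient=True, **kw)


# ------------------------------------------------------------- analysis

def outlet_symmetry_gap(result: UQResult,
                        pair: tuple = ("outlet0_mean", "outlet1_mean"),
                        quantities: tuple = ("pressure", "velocity"),
                        junction_exclusion: float = 1.0) -> float:
    """Mirror asymmetry of first-order Sobol profiles between outlets.

    Compares the Sobol profile of the branch-outlet parameter along the
    branch axis with that of the main-outlet parameter along the
    downstream limb of the main axis, resampled onto a common
    normalised distance-from-junction coordinate; returns the largest
    absolute gap.  Sites within ``junction_exclusion`` radii of the
    junction are excluded: there the two "axes" traverse the shared
    junction cavity (the branch staircase cuts through it), so they do
    not parameterise distinct limbs.
    """
    cfg = result.config
    domain = build_bifurcation(BifurcationSpec(
        radius=cfg.radius, include_branch=cfg.include_branch))
    p0 = domain.channels.p0
    nm = domain.main_axis_sites.size
    dn = slice(nm // 2, nm)
    dist_m = np.linalg.norm(
        domain.fluid_idx[domain.main_axis_sites[dn]] - p0, axis=1)
    dist_b = np.linalg.norm(
        domain.fluid_idx[domain.branch_axis_sites] - p0, axis=1)
    rmin = junction_exclusion * cfg.radius
    sel_m = dist_m > rmin
    sel_b = dist_b > rmin
    xm = (dist_m[sel_m] - rmin) / (dist_m.max() - rmin)
    xb = (dist_b[sel_b] - rmin) / (dist_b.max() - rmin)
    gaps = []
    for q in quantities:
        qb = result.qois.get(f"{q}_branch")
        qm = result.qois.get(f"{q}_main")
        if qb is None or qm is None:
            raise CampaignError("symmetry gap needs both branch and main QoIs")
        names = qm.sobol.input_names
        i0, i1 = names.index(pair[0]), names.index(pair[1])
        sb = qb.sobol.first_order[i0][sel_b]
        sm = qm.sobol.first_order[i1][dn][sel_m]
        gaps.append(np.max(np.abs(np.interp(xm, xb, sb) - sm)))
    return float(max(gaps))
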