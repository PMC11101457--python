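# lbmuq

Uncertainty quantification of lattice Boltzmann haemodynamics in
bifurcating vessels.

Vascular CFD results depend on numerical knobs (grid spacing `dx`, time
step `dt`, number of steps) and on boundary data (inlet peak velocity,
sinusoidal outlet pressure mean/amplitude/period/phase) that are never
known exactly.  `lbmuq` measures how that input uncertainty propagates
into the pressure and velocity fields of a canonical arterial junction:
a circular channel of length 10R along +x with a side branch of length
5R leaving the midpoint at 45°, voxelised procedurally and solved with a
D3Q19 BGK lattice Boltzmann kernel (Ladd parabolic velocity inlets,
Nash-style phantom-site sinusoidal pressure outlets, Bouzidi
interpolated walls; blood as a Newtonian fluid, ρ = 1000 kg/m³,
μ = 4 mPa·s).

The statistics core is non-intrusive polynomial chaos: inputs
`ξ ~ U[a,b]` are sampled on a full tensor Gauss–Legendre grid
(`N = (p+1)^k` runs), a PCE `q(ξ) = Σ_j c_j P_j(ξ)` in orthonormal
Legendre products is fitted by spectral projection, and from the
coefficients follow the output mean/variance, 1%/99% bands, Sobol
variance shares `S_u = D_u / D` (summing to one over the subset
lattice), and the coefficient-of-variation ratio

    CVR = CV(q) / CV(ξ) = (1/M Σ σ_q/μ_q) / (1/D Σ σ_ξ/μ_ξ),

which says whether the solver amplifies (CVR > 1) or damps input
variability.  A stochastic-collocation surrogate and a double-loop
Monte-Carlo estimator cross-check the PCE machinery.

## Worked example

A two-input campaign on the radius-6 bifurcation using the fast
analytic resistor-network runner (swap `runner="lbm"` for the real
solver; everything else is identical):

```python
from lbmuq.campaign import CampaignConfig, run_campaign
from lbmuq.uq_engine import InputSpec

cfg = CampaignConfig(
    name="demo", radius=6, order=2, runner="analytic",
    inputs=[InputSpec("inlet_max", 0.0, 0.005),        # m/s
            InputSpec("outlet0_mean", 0.0, 0.00025)],  # mmHg
    fixed={"steps": 1500})
res = run_campaign(cfg)
qa = res.qois["velocity_branch"]
print("nodes:", res.n_nodes)
print("cv_q %.4f cv_xi %.4f cvr %.4f" % (res.cv_q, res.cv_xi, res.cvr))
print("S(inlet_max) at branch outlet: %.4f" % qa.sobol.first_order[0][-1])
```

prints

```
nodes: 9
cv_q 0.5640 cv_xi 0.5774 cvr 0.9770
S(inlet_max) at branch outlet: 0.9994
```

Nine runs (two inputs at order 2), an output coefficient of variation
slightly below the input one (CVR ≈ 0.98: the near-linear creeping-flow
response passes variability through essentially unchanged), and the
inlet velocity owning 99.9% of the velocity variance at the branch
outlet — the tiny outlet-pressure range cannot compete.

The solver itself is verified against Poiseuille flow:

```sh
$ lbmuq verify poiseuille --radius 10 --steps 4000
L_inf profile error: 0.57% of U (305 sites, 4000 steps)
```

Campaign presets carrying the reference input ranges are available from the
CLI, e.g.

```sh
lbmuq campaign run --preset BC1 --scale 0.3 --order 1 --out runs/bc1
```

which writes per-QoI CSV tables (mean, std, quantiles, one Sobol column
per input, lumped higher orders) and a `summary.json` with CV(q), CV(ξ)
and CVR.  Completed runs are cached by configuration hash, so an
interrupted campaign resumes where it stopped.

## Layout

| module | contents |
|---|---|
| `lbmuq.geometry` | voxel bifurcation/cylinder builder, wall distances, centrelines, inlet weights |
| `lbmuq.lbm_core` | D3Q19 constants, equilibrium/moments/collision, unit system |
| `lbmuq.boundaries` | Ladd inlet, phantom pressure outlet, Bouzidi walls, waveforms |
| `lbmuq.solver` | the time-stepping driver |
| `lbmuq.qoi` | centreline profiles and plane velocity series |
| `lbmuq.uq_engine` | tensor quadrature, PCE, collocation, Sobol, CV/CVR |
| `lbmuq.campaign` | presets, orchestration, caching, analysis outputs |
| `lbmuq.reference_models` | analytic oracles (Poiseuille, resistor network, Sobol test functions) |
| `lbmuq.io` / `lbmuq.cli` | HDF5/VTK export, command-line layer |

See `docs/methods.md` for the model details, parameter conventions and
the limitations of the reduced-scale campaigns.
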