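# Methods

`lbmuq` quantifies how algorithmic and boundary-condition parameters of a
D3Q19 lattice Boltzmann (LB) solver propagate into the pressure and
velocity fields computed in an idealised vascular bifurcation.  This note
documents the models, the numerical choices, and what the reduced-scale
test campaigns do and do not demonstrate.

## Flow model

The solver is a single-relaxation-time (BGK) lattice Boltzmann kernel on
the D3Q19 velocity set.  Populations `f_i` evolve by

    f_i(x + c_i, t+1) = f_i(x, t) - (1/tau) (f_i - f_i^eq),

with the second-order Maxwellian equilibrium

    f_i^eq = w_i rho (1 + c_i.u/Cs^2 + (c_i.u)^2/(2 Cs^4) - |u|^2/(2 Cs^2)),

`Cs^2 = 1/3`, weights 1/3, 1/18 (x6), 1/36 (x12).  Density and momentum
are the zeroth and first moments; pressure is `Cs^2 (rho - 1)` scaled to
physical units.  The relaxation time follows from the kinematic
viscosity and the discretisation,

    nu = Cs^2 (tau - 1/2) dx^2 / dt,

the dimensionally consistent form of the viscosity relation.  The fluid
is Newtonian blood: density 1000 kg/m^3, dynamic viscosity 4 mPa.s, so
`nu = 4e-6 m^2/s`; for the reference discretisation `dx = 5e-5 m`,
`dt = 6e-5 s` this gives `tau = 0.788`.  Fields are initialised at rest
at the reference pressure (0 mmHg).  Runs abort with a diagnostic naming
the step and site if any density leaves [0.1, 10] or becomes non-finite.

Streaming is implemented as a pull over a precompiled gather table; the
contract is that one collide+stream advances every fluid site exactly
once.  The step is allocation-free after set-up (~2 ms per step at 1e4
fluid sites).

## Geometry

The canonical domain is the union of capped circular cylinders: a main
channel of length ten radii along +x and (optionally) a side branch of
length five radii leaving the main-channel midpoint at 45 degrees in the
x-y plane.  A site is fluid iff its centre lies strictly inside the
union laterally; the cap planes are closed so inlet/outlet sites sit
exactly on them.  A 1e-9 guard band on the squared radius makes the
strict inequality deterministic for site centres that fall exactly on
the surface (they count as solid).  The junction is a plain solid union
(no fillet).  Outlet 0 is the side branch and outlet 1 the main channel
— a package convention, fixed and documented here because the labels'
physical assignment is otherwise arbitrary.

For every fluid-to-solid link the fraction `q` of the link cut by the
continuous surface is found by bisection (60 iterations, far below the
1e-10 tolerance) on the implicit membership function; these fractions
feed the interpolated wall rule.  Centrelines are extracted by sampling
the continuous axis at 0.05-lattice-unit steps, taking nearest sites,
deduplicating, and completing diagonal moves into a 6-connected chain;
a straight axis of length L yields L+1 sites and the 45-degree branch
about `ceil(5R sqrt(2))` sites.

## Boundary conditions

* **Walls** use the Bouzidi linear-interpolation rule in its two
  branches (q < 1/2 and q >= 1/2); at q = 1/2 it reduces exactly to
  simple bounce-back.  Where the q < 1/2 branch needs an upstream fluid
  neighbour that does not exist (thin gaps), plain bounce-back is used.
* **Velocity inlets** use bounce-back plus the Ladd correction
  `-2 w_i rho u.c_i / Cs^2`, with a parabolic weight map
  `w = max(0, 1 - (r/R)^2)` scaling a maximum-velocity program.
  Steady programs can ramp from rest over a half-cosine window (the
  steady state is unaffected; the ramp merely softens the acoustic
  start-up transient); the transient program is a half-cosine ramp to a
  base velocity followed by a single smooth sin^2 pulse.
* **Pressure outlets** use the phantom-site construction: the unknown
  inbound populations are the equilibrium populations of a fictitious
  site carrying the imposed density and the boundary site's normal
  velocity component (tangential components zero) — a mixed
  Dirichlet-Neumann closure, first-order accurate.  The imposed value
  follows `p(t) = mean + amplitude sin(2 pi t / period + phase)`; the
  sine-with-offset-phase convention is fixed here (the four parameter
  names do not by themselves determine the functional form).
  Equilibrium-only phantom populations are used (no non-equilibrium
  extrapolation): in steady Poiseuille tests the variants that keep the
  non-equilibrium part, or use anti-bounce-back, leave the same residual
  — a constant offset of roughly three lattice units times the local
  axial gradient at the cap — so the simplest construction is kept.
  This first-order cap artifact means imposed outlet pressures are
  honoured only up to O(grad dx); it is visible in short tubes and
  negligible for vessels hundreds of voxels long.

Verification: in a radius-10 cylinder at Re = 0.25 the steady velocity
profile matches the Poiseuille parabola with L_inf error ~0.6% of the
centreline velocity (<3%, improving with resolution), the axial pressure
profile is linear (R^2 > 0.999), and mass is conserved to 1e-12 relative
over 100 periodic steps.

## Uncertainty quantification

Inputs are independent uniforms on physical ranges fixed by the campaign presets.  A full
tensor product of (p+1)-point Gauss–Legendre rules supplies
`N = (p+1)^k` model evaluations.  A polynomial chaos expansion in
orthonormal Legendre products is fitted by spectral projection; with an
orthonormal basis the mean is the zero-index coefficient, the variance
the sum of remaining squared coefficients, and Sobol variance shares are
partial sums of squared coefficients grouped by multi-index support, so
all subset indices sum to one by construction.  A stochastic-collocation
(tensor Lagrange) surrogate through the same node values serves as an
independent cross-check: the two agree to 1e-10 on models of
per-dimension degree <= p, and the PCE Sobol indices agree with a
double-loop Monte-Carlo estimator (1e5 outer x 1e3 inner, seeded, with
an inner-noise bias correction) to well within 0.02 on the analytic test
functions.

Distribution summaries report the analytic mean/std plus 1% and 99%
quantiles from 1e5 seeded surrogate samples (seed 20240517 by default;
every consumer can pass its own).  The coefficient-of-variation ratio is

    CVR = CV(q) / CV(xi),

where `CV(xi)` averages sigma/mu over the input uniforms (closed form:
`((b-a)/sqrt(12)) / ((a+b)/2)`) and `CV(q)` averages sigma/|mu| over all
scalar QoI components; components with |mu| < 1e-15 are excluded (the
ratio diverges there) and the exclusion count is logged.  The symbol
`D` is used in the literature for both the input count and the total
variance; the code names them `input_count` and `total_variance`.

## Campaigns

A campaign fixes the lattice geometry and executes the solver at every
quadrature node.  `voxel_size` and `step_length` act through the unit
system (tau, velocity/pressure scales, implied physical size), which is
exactly how a fixed pre-processed lattice experiences discretisation
uncertainty; rebuilding the lattice per node would change the axis site
counts and make the per-index QoI vectors non-alignable across nodes.
`steps` is an integer input; quadrature nodes are rounded to the nearest
whole step.  Runs are cached under a SHA-256 hash of the canonicalised
run configuration, so interrupted campaigns resume without re-running
completed nodes, and identical configurations reproduce bitwise
identical CSV outputs (cache files are written at %.17g and parsed in
round-trip mode).  A diverged node aborts the campaign naming its
parameters.  Each campaign logs per-run tau and maximum lattice Mach
number and the Reynolds bound over the input hull.

Presets carry the reference ranges: the algorithmic campaign varies
`dx in [5e-5, 1.5e-4] m`, `dt in [6e-5, 1.2e-4] s`,
`steps in [2500, 5000]` around a 0.001 m/s inlet; its "converged"
variant multiplies the step counts by ten.  The boundary campaigns fix
the discretisation and vary the inlet maximum (0–0.005 m/s) and the
sinusoidal outlet parameters (mean/amplitude 0–0.00025 mmHg, period 1–2 s,
phase 0–0.05 rad) in the combinations BC1 (inlet + branch outlet),
BC2 (inlet + main outlet), BC3 (both outlets, period fixed, inlet
fixed), BC4 (inlet + both means and amplitudes).  A transient preset
emulates the pulsatile personalised-artery study: ramped initialisation
over the first half of the run, a heartbeat-like pulse in the second
half, plane mean/max velocity series (32 samples) as QoIs, and
outlet mean/amplitude ranges of 0–0.2 mmHg.

### Reduced-scale study conditions

Full-resolution campaigns (radius 20–40, up to 50000 steps, third order)
take CPU-days.  The test and acceptance campaigns run the same presets
at `scale = 0.3` — lattice radius 6, step counts scaled in proportion —
with first-order expansions, sizes chosen so the whole battery completes
in minutes on one core.  At radius 6 the flow is steady to machine
precision within ~5000 steps, so the "converged" variant (9000–13400
steps at its quadrature nodes) is genuinely converged, and the
first-order grids are exact for the near-linear creeping-flow responses
involved.  These reduced campaigns reproduce the study's qualitative
findings: the step count loses all influence once runs are converged
(S(steps) ~ 1e-12), the inlet velocity controls >99% of the velocity
variance when it is varied, and varying both outlets produces mirrored
Sobol profiles between the branch and main limbs.

The mirror comparison excludes sites within one radius of the junction:
there the branch "axis" staircase traverses the shared junction cavity,
where velocity variance is ~100x smaller and the index is dominated by
discretisation noise; beyond that zone the profiles agree to better
than 0.01.  Wall no-slip is likewise assessed as the excess over the
analytic profile at wall-adjacent sites (their centres sit ~1 voxel
inside the wall, where a resolved parabola is itself non-zero).

What the reduced campaigns do **not** show: grid-convergence behaviour
at full resolution (radius 20-40), the full-scale CV(q)/CVR magnitudes (these
depend on domain size and step counts), higher-order Sobol structure
(first-order grids lump all interactions), or any feature of real
patient geometries — the synthetic bifurcation has perfectly circular
sections, exact 45-degree planar branching and rigid walls.

## Analytic stand-ins

`reference_models` provides the oracles that make the pipeline testable
without simulations: the Poiseuille solution (profile, flow rate,
pressure drop `4 mu L U / R^2`), a three-resistor bifurcation network
(junction losses neglected — legitimate at Re << 1, where boundary
data rather than geometry controls the flow split) that emits QoI
vectors of the same shape as a lattice run, Sobol test functions with
closed-form decompositions (`xi1`, `xi1 + xi2`, `xi1 xi2` with indices
1; 1/2, 1/2; 3/7, 3/7, 1/7), and the double-loop Monte-Carlo estimator.

## Known limitations

* The phantom pressure outlet is first-order: imposed values are
  honoured up to ~3 lattice units of local gradient at the cap.
* BGK with tau far from 1 (large dt, small dx) degrades accuracy before
  it destabilises; campaigns log tau so outliers are visible.
* The transient preset emulates the shape, not the values, of a
  clinical inlet waveform.
* Newtonian rheology, rigid walls, no wall-shear-stress QoIs.
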