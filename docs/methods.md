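# Methods

## Model structure

The population state is the density n(a, t) of cells over intracellular ALP
activity a ≥ 0 (activity units; time in days). Four single-cell processes
enter the balance equation:

* **Division** with daughter-pair kernel k_d(a, a′) (per day). Two modes:
  *conserved* divisions split the parent activity a + a′ into daughters
  (a, a′) and leave the first moment Φ invariant; *non-conserved symmetric*
  divisions give both daughters the parent's activity. The latter is the
  delta kernel k·δ(a − a′); we never discretize the delta — the mode flag
  makes the solver use the exact local reduction g(t)·k·n(a, t).
* **Terminal differentiation** removes cells at rate k_f(a) (per day).
* **ALP synthesis / degradation** drift a cell's activity at net velocity
  v(a) = s_i(a) − d_o(a) (activity units per day); in the balance equation
  this is the conservative term −∂(v(a)·n)/∂a.

Time dependence of division is kept separable: kernels are
time-independent and a scalar factor g(t) multiplies the division terms.
The presets use amplitude k = 1 with g(t) = 2/t, the choice that converts
exponential moment growth dN/dt = k_d·N into the quadratic law N = N̄₀·t²
observed in scaffold cultures. Because 2/t diverges at t = 0, every
integration starts from a strictly positive t₀; the package default
reference day is t₀ = 7, the first assay measurement, used when converting
fitted amplitudes (N̄₀, Φ̄₀) into initial-time values (N₀, Φ₀). The
reference day is configurable everywhere; published initial-time ALP values
rarely state their reference day, so amplitudes are the primary
parameterization and initial-time values are derived quantities.

A note on the degradation term: writing the ALP out-flux
non-conservatively (−d_o·∂n/∂a, with constant d_o) would make the moment
balance lose cells instead of activity. With the activity-proportional flux
d_o(a) = d₀·a in conservative form, the moment equations close exactly:
dN/dt = g·k·N and dΦ/dt = (g·k − d₀)·Φ, whose solutions are the PSCD
closed forms N̄₀·t² and Φ̄₀·t²·e^(−d₀·t). The package implements the
conservative form throughout.

## Numerical solver

Finite-volume discretization on a fixed activity grid; explicit Euler
(default) or Heun time stepping with a CFL guard that refuses unstable
steps and names the largest stable one. Advection fluxes are first-order
upwind by default, with an optional van-Leer-limited MUSCL reconstruction.
Conserved-division integrals use midpoint (rectangle) weights on a uniform
grid: for a symmetric kernel the discrete gain and loss pair along
anti-diagonals, so the discrete Φ is conserved to round-off (measured drift
~1e-10 % over 28 days). Moments are always reported by trapezoidal
quadrature. Densities are clipped at −1e-12 after each step.

**Grid choice matters for the PSCD configuration.** Under pure degradation
the distribution contracts as e^(−d₀·t); over 21 days at d₀ = 1/5.84 that
is a ~36-fold shrinkage. On a uniform grid the upwind scheme's numerical
diffusion (modified-equation coefficient |v|Δa/2 with v = −d₀a) then
inflates Φ by order 100% — no uniform 400-point grid can track the
collapsing support. A *geometric* grid makes the linear drift a constant
velocity in log-activity, and with the MUSCL flux plus Heun stepping the
moment error over a 7→28-day run is ≤ 0.2% at 400 points and 2000 steps.
The quantitative tests and the acceptance script therefore use
`spacing="geometric"`, `scheme="heun"`, `flux="muscl"`; the plain
upwind/uniform default remains for its transparent first-order convergence
(halving Δa and Δt reduces moment error by ≈2×, verified in the tests).

Boundary handling: zero inflow at a_max; outflow through a = 0 occurs only
if the drift is negative there — for d_o(a) = d₀·a it vanishes, so cell
number is untouched by degradation (verified to 1e-6). Any a = 0 outflow is
accumulated and reported on the moment series rather than silently dropped.

The initial shape n(a, t₀) is not constrained by the assays (only its
moments are); the demonstration default is a gamma density (shape 2), and
the solver tests check that the moment trajectories are shape-independent.

## Stochastic single-cell simulator

An exact event-driven simulation of the same processes: per-cell division
rate g(t)·k, removal rate k_f(a), deterministic drift between events
(integrated exactly when a closed form exists, e.g. a·e^(−d₀Δt) for linear
degradation; otherwise midpoint substeps of 0.01 day). The time-dependent
rate 2/t is handled by Ogata thinning with the majorant evaluated at the
interval start — valid because the factor is non-increasing; a majorant
violation raises instead of biasing. The conserved-division split is
uniform on [0, a] by default (the kernel shape is not identified by moment
data; the tested properties are split-independent). Replicate r of an
ensemble run uses seed + r; a fixed seed reproduces a trajectory exactly.

Against the mean-field closed forms, 500-replicate ensemble means of N and
Φ agree within 3 Monte-Carlo SE at all recorded days (acceptance check;
typical max |z| ≈ 0.7–1.4).

## Fitting

* Cell counts: N(t) = N̄₀·t² is linear in N̄₀; the weighted least-squares
  estimate is closed-form (Σw·t²·y / Σw·t⁴, w = 1/σ²), and a test verifies
  it coincides with an independent iterative optimizer. Datasets from
  conditions with indistinguishable growth can be pooled.
* ALP: Φ(t) = Φ̄₀·t²·e^(−d₀·t) by bounded nonlinear least squares with an
  analytic Jacobian, initialized from the exact log-linear transform
  ln Φ − 2 ln t = ln Φ̄₀ − d₀·t; when non-positive ALP means make the
  log-init unusable the initializer falls back to a profile grid search
  over d₀ ∈ [1/50, 2] per day. Non-convergence is flagged on the result,
  never silent.
* Goodness of fit: the SD-weighted χ² = Σ((y − f)/σ)² and the unweighted
  residual sum of squares are both reported, since published χ² values
  often leave the weighting convention unstated.
* Uncertainty: SEs from the Jacobian covariance scaled by reduced χ²
  (the convention of standard fitting software; invariant to a common
  rescaling of the σ column, so it is insensitive to whether σ is the
  replicate SD or the SE of the mean). **Confidence intervals use
  Student-t quantiles at the fit's residual dof.** With four assay days
  and two ALP parameters, dof = 2 and the 97.5% t quantile is 4.30; a
  normal 1.96·SE interval covers the truth only ~77% of the time in
  simulation, while the t-based 95% interval covers ~93%. The
  parameter-recovery acceptance check uses the t-based interval.
* Condition comparison reports d₀ for both conditions, their ratio, and
  the difference of decay times 1/d₀ with propagated SE; the verdict
  "slower ALP degradation under field" requires the ratio to differ from 1
  by more than one combined SE.
* Model discrimination fits both ALP laws and flags the instantaneous
  model whenever the empirical ALP maximum is at an interior day — the
  monotone t² law cannot produce that — in addition to comparing χ².
  No multiplicity correction is applied: two conditions, one
  pre-specified comparison.

## Synthetic assay generator

Emulates the assay design: days {7, 14, 21, 28}, four samples per
condition, replicate observations drawn Normal(truth, CV·truth) truncated
at zero, summarized as per-day mean and sample SD. Default CVs are 10%
(counts) and 5% (ALP) — chosen once to resemble the relative error bars
typical of LDH/ALP assays; the true replicate-level variance structure of
any particular experiment is generally unpublished, so these are free
parameters. The reference truth pair is N̄₀ = 535 cells/day² for both
conditions, with (Φ₀ = 0.8007, 1/d₀ = 5.84 days) for control and
(Φ₀ = 0.84, 1/d₀ = 6.2 days) for the stimulated condition at reference day
7 — ALP peaks at 11.68 vs 12.4 days.

What passing tests on generated data do show: the estimators are unbiased
at these noise levels (mean recovered 1/d₀ within 0.2% over 200 datasets),
interval coverage is near nominal, and the progressive/instantaneous
discrimination is essentially certain at 5% ALP noise. What they do not
show: robustness to non-Gaussian or day-dependent measurement error,
between-donor heterogeneity, or calibration-curve nonlinearity in the
underlying colorimetric assays — none of which the generator emulates.

## Problem sizes

Default quantitative configurations: PDE runs with 400 grid points and
2000 steps (≈1 s); 500 agent replicates starting from 24 cells at day 7
(≈4 s); 200-dataset recovery studies and 100-seed discrimination studies
(seconds). These sizes hold every acceptance quantity's Monte-Carlo error
well below the tolerances being checked.

## Known limitations

* No spatial structure, migration, or field-strength response functions:
  the electric field enters only as a condition label at the fitting
  stage, and with two field levels (0 and 3.6 mV/cm) only a two-point
  comparison of d₀ is possible, not a functional form d₀(|E|).
* The division-rate/density relation derived from k_d = 2/t and N ∝ t² is
  exactly k_d ∝ ρ^(−1/2); the package reports this exact exponent rather
  than any stronger inverse-proportionality claim.
* The conserved-division kernel is unidentifiable from moment data; the
  PDE path and the agent path use different but moment-equivalent
  representations of it, and are only cross-validated in the
  non-conserved (symmetric) mode.
* Explicit time stepping only; stiff kernel choices (large rates) require
  correspondingly many steps, enforced by the CFL guard.
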