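# Methods

## Model

The cascade couples five clinical biomarkers by one-directional drives:
amyloid grows logistically toward a carrying capacity `K_Aβ`; amyloid
drives tau phosphorylation toward `K_τp`; a second, amyloid-independent
tau component grows linearly with age (aging/SNAP); both tau components
drive neurodegeneration toward `K_N`; neurodegeneration and
phosphorylated tau drive cognitive impairment toward `K_C`. All rates
are per year and every trajectory starts from subject-specific initial
conditions at the reference age `T0 = 50` (just below the youngest age
the sampling designs assume). The model is deliberately sparse — each
biomarker has one or two drivers — so that per-subject longitudinal
series with a handful of visits can constrain it.

Assumptions worth keeping in mind: all interactions are monotone
(states never decrease without treatment), capacities are fixed
per-subject constants, and the therapy enters purely as a clearance
term `−u(t)Aβ` — there is no pharmacokinetic layer between dose and
clearance rate, and no spatial structure.

The package works entirely in model space. Raw CSF Aβ42 *decreases*
with disease burden while the modeled brain amyloid burden increases;
the transformation from raw assay values into model units is left to
the user (as is the choice of mapping total tau vs. total-minus-
phosphorylated tau onto `τo`).

## Calibration

Per subject, the fit minimizes the summed squared residuals of all
observed biomarkers at their visit ages, unweighted by default (an
optional per-biomarker weight dict is accepted). The 16-parameter
problem is non-convex, so the solver is warm-started equation by
equation in cascade order: amyloid first (closed form, no integration),
then `τp`, `τo` (exact linear form), `N`, and `C`, each stage fitting
only its own parameters with upstream estimates frozen; the `C` stage
fits `(λ_CN, K_C, C0)` and leaves the tau coupling `λ_Cτ` to the joint
refinement. Each stage and the joint refinement use bounded
trust-region least squares (SciPy `least_squares`/trf, tolerances
1e−14, a few deterministic rate-scaled restarts per stage). The joint
step never returns a point worse than its warm start: solver failure or
non-improvement falls back to the sequential estimate with a warning
flag.

Default bounds: rates in `[0, 10× largest published group mean]`,
capacities in `[max observed value, 10× max observed]`, initial
conditions in `[0, capacity bound]`. Inclusion rule: at least three
longitudinal datapoints per fitted biomarker; violations raise an
explicit exclusion error. Flat or saturated series are flagged as
unidentifiable and given the deterministic zero-rate/flat fit rather
than an arbitrary interior point.

The reported relative error per biomarker is the mean absolute relative
deviation (the printed rendering of this statistic is ambiguous between
absolute and squared forms; `form="rmsre"` switches to the
root-mean-square version).

## Treatment optimization

The objective penalizes terminal amyloid and cognition (weights
`α₁ = α₂ = 1`), accumulated cognitive burden, and a quadratic dosing
cost with weight `ε(Aβ, t) = ε₀ Aβ e^{−γ(t−T₁)}` (`ε₀ = 5`, `γ = 2`/yr):
side-effect risk (ARIA) scales with amyloid burden and concentrates
early in treatment. The time argument of `ε` is time on treatment, not
absolute age. The control set is `0 ≤ u ≤ u_max` with `u_max` from the
drug registry, converted from per-week to per-year with a factor 52;
78 weeks is 1.5 years and 76 weeks is 76/52 years exactly.

Necessary conditions follow from the Pontryagin Maximum Principle. Two
details are configuration choices:

- `adjoint_form="derived"` (default) uses the full `−∂H/∂C` derivative,
  which includes a `λ_Cτ τp/K_C · Λ₅` term; `"printed"` reproduces the
  commonly quoted reduced form that omits it (the two coincide whenever
  `λ_Cτ = 0`).
- The clamp is the standard `min(u_max, max(0, Λ₁Aβ/2ε))`; when `ε`
  vanishes (amyloid fully cleared) the update degenerates to bang-bang.

The optimality system is solved by forward–backward sweep: forward RK4
state solve, backward RK4 adjoint solve on the same grid (states and
control linearly interpolated at half-steps), pointwise clamped control
update, then relaxation `u ← 0.5·u_new + 0.5·u_old`. Convergence is the
maximum over the state/adjoint/control blocks of the relative sup-norm
change, tolerance 1e−4, cap 500 iterations; if the objective rises for
five consecutive sweeps the relaxation weight is halved. The control
starts from zero. Typical problems converge in 10–25 sweeps.

## Numerical choices

- Fixed-step classical RK4 on a uniform grid (default 0.01 yr) for both
  states and adjoints, so the two solves share one grid; kernels are
  numba-compiled with a pure-Python fallback of identical semantics.
- Pre-treatment burn-in: trajectories always start at `T0 = 50` and are
  integrated untreated to the treatment start, so the state at `T1` is
  model-consistent rather than a free input.
- A state that lands below zero after a step is clipped to zero if the
  undershoot is within 1e−9 (round-off guard, states have magnitudes up
  to ~260); anything larger is reported as an integration failure with
  the offending time.
- Objective integrals use the composite trapezoid rule on the grid.
- Model values at observation ages are linear interpolants of the grid
  solution; the cohort generator and the calibration forward model share
  this code path, so noiseless synthetic data is exactly realizable.

## Synthetic cohorts

The generator emulates the sampling design of a multicenter natural
history study: CSF-like measures (`Aβ`, `τp`, `τo`) every 2 years over a
10-year follow-up, `N` yearly, `C` every 6 months, baseline ages uniform
on 54–85, multiplicative Gaussian noise with per-biomarker CVs
(5% CSF, 1% volumetric, 10% cognitive). Parameters are independent
truncated normals with the published per-group means and standard
deviations (AD n=10, LMCI n=32, CN n=7; no correlations are published,
so none are modeled), floored at 1e−6 with initial conditions capped at
their capacities. Carrying capacities are floored at 5% of their group
mean instead: several published stds exceed their means, and a capacity
far below the biomarker's scale is biologically meaningless while
making the logistic terms too stiff for a fixed-step integrator.
Everything is deterministic under the spec's seed.

What the generator does *not* capture: dropout, assay batch effects,
left-censoring, visit jitter — and, importantly, the parameter
*correlations* of real subjects. Sampling the published means and
standard deviations independently produces joint dynamics faster than
any real fitted subject: `τp`, `N` and `C` typically saturate before or
within the visit window. Two consequences, both observed and flagged by
the package itself:

1. Saturated series carry no information about their rates, so several
   parameters of such subjects are structurally unidentifiable (the fit
   reproduces the data to ~1e−10 SSE while the rates are undetermined).
2. A subject whose cognition has plateaued cannot benefit from amyloid
   clearance, so published-statistics cohorts are almost entirely
   non-responders (consistent with the many "NR" entries in the
   published per-subject tables).

Validation studies that need identifiable parameters or measurable
treatment responses therefore use the documented
`SLOW_PROGRESSION_STATS` benchmark (10% relative spread around means
chosen to keep every biomarker in its dynamic phase through roughly
ages 54–80, baseline window 54–60). Passing tests on this benchmark
demonstrate that the calibration and control machinery is correct in
the identifiable regime; they do not certify recovery on saturated
real-world series, which the package instead reports via
unidentifiability flags.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` use: a 40-year integration
against the closed-form amyloid solution (4001 grid points, agreement
~1e−14); finite-difference checks of the adjoint-based Hamiltonian
gradient at interior grid nodes (relative agreement ~1e−6); a
brute-force oracle that optimizes 8 piecewise-constant control values
with an independent adaptive integrator (LSODA) — the sweep objective
lands within 1% of (in practice below) the oracle optimum; noiseless
recovery on a 10-subject benchmark cohort (~1e−10 relative error on all
16 parameters); a 20-replicate noise study at 5% CV in which the
amyloid growth-rate estimator is unbiased to within a few percent while
its per-fit median absolute error (~24%) reflects the information floor
of a 6-visit, 3-parameter logistic design; and a 12-arm in-silico trial
(3 drugs × start ages 60/70 × 78 weeks/10 years) whose arm medians
respect the dose, duration and start-age orderings.

## Known limitations

- No uncertainty quantification beyond the Monte-Carlo recovery
  harness; fits are point estimates.
- Subjects are fit independently; no hierarchical pooling.
- The side-effect parameters `(ε₀, γ)` are plain configuration values;
  their published derivation cannot be reproduced self-consistently
  under any single unit convention, so the quoted defaults are adopted
  as-is.
- Necessary-condition optimality only: the sweep is checked against
  discretized brute force, not certified globally optimal.
- The cognitive-percentage-change metric divides by untreated cognition
  at `T2`; it is undefined (and treated as no-response) when that value
  is zero.
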