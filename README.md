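# adcascade

Personalized modeling of the Alzheimer's disease biomarker cascade and
optimal planning of anti-amyloid-beta therapy.

The package is for computational researchers in disease-progression
modeling who want to (i) fit a mechanistic biomarker cascade to one
subject's longitudinal data, (ii) derive drug clearance limits from
published trial outcomes, and (iii) compute a personalized, time-varying
dosing schedule by optimal control — all testable end-to-end on
synthetic cohorts with known ground truth, without access to any
restricted clinical dataset.

## The model

Five biomarkers evolve along the amyloid cascade, with ages and rates in
years: amyloid burden `Aβ`, phosphorylated tau `τp`, age/SNAP-related tau
`τo`, neurodegeneration `N`, and cognitive impairment `C` (ADAS13-like,
higher is worse):

```
dAβ/dt = λ_Aβ Aβ (1 − Aβ/K_Aβ) − u(t) Aβ
dτp/dt = λ_τ Aβ (1 − τp/K_τp)
dτo/dt = λ_τo
dN/dt  = (λ_Nτo τo + λ_Nτp τp)(1 − N/K_N)
dC/dt  = (λ_CN N + λ_Cτ τp)(1 − C/K_C)
```

`u(t)` is the anti-amyloid clearance rate of the therapy. Untreated
amyloid has the closed-form logistic solution used for calibration and
as an integration oracle.

**Calibration** fits all 16 parameters (11 rates/capacities + 5 initial
conditions at reference age `T0 = 50`) per subject by nonlinear least
squares, warm-started equation-by-equation in cascade order and then
refined jointly. **Treatment planning** minimizes

```
J(u) = α₁Aβ(T₂) + α₂C(T₂) + ∫ C dt + ∫ ε(Aβ,t) u² dt,   0 ≤ u ≤ u_max,
ε(Aβ,t) = ε₀ Aβ e^{−γ(t−T₁)}
```

via Pontryagin's Maximum Principle: adjoint dynamics `Λ' = −∂H/∂x` with
transversality conditions `Λ₁(T₂)=α₁`, `Λ₅(T₂)=α₂`, optimality condition
`u* = clamp(Λ₁Aβ/2ε, 0, u_max)`, solved by forward–backward sweep on a
shared fixed RK4 grid. `u_max` comes from trial-reported amyloid
reductions (`u_max = −ln(remaining fraction)/weeks`): aducanumab
2.31×10⁻³/wk (low dose) and 4.07×10⁻³/wk (high dose), donanemab
2.00×10⁻²/wk.

## Worked example

```
$ python examples/04_optimal_treatment.py
sweep converged in 14 iterations (objective J = 145.43)
weeks on treatment | clearance rate u (/year)
                 0 | 0.0706  (u_max = 1.0418)
                19 | 0.1507  (u_max = 1.0418)
                39 | 0.3357  (u_max = 1.0418)
                58 | 0.7677  (u_max = 1.0418)
                78 | 1.0418  (u_max = 1.0418)

terminal amyloid: 74.4 treated vs 145.6 untreated
terminal cognition: 18.580 treated vs 18.589 untreated  (0.050% less decline)
```

The optimal donanemab schedule for a 78-week course starting at age 60
ramps up as the amyloid-dependent side-effect weight decays, hitting the
clearance ceiling late — the titration pattern used in actual trials.
Amyloid is halved; the cognitive benefit over 78 weeks is modest
(0.05% less decline), consistent with short anti-amyloid courses having
large amyloid but small cognitive effects. The other example scripts
cover simulation (`01`), drug-rate derivation (`02`), calibration with
ground-truth recovery (`03`), and a 12-arm in-silico trial (`05`).

A thin CLI exposes the same pipeline:
`adcascade synth|calibrate|optimize|trial --help`.

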