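"""Calibrate one synthetic subject and compare against the ground truth.

Generates a noiseless slow-progression subject (all five biomarkers in
their dynamic phase over the visit window), runs the sequential
equation-by-equation warm start followed by joint refinement, and
prints recovered vs. true parameters.
"""

from adcascade import calibrate, generate_cohort
from adcascade.cohort import slow_progression_spec
from adcascade.reference import PARAM_ORDER

cohort = generate_cohort(slow_progression_spec(n=1, seed=3, noiseless=True))
truth, record = cohort.subjects[0], cohort.records[0]

result = calibrate(record)

print(f"{'parameter':15s} {'true':>12s} {'recovered':>12s} {'rel err':>10s}")
for name in PARAM_ORDER:
    t = getattr(truth, name)
    f = getattr(result.params, name)
    print(f"{name:15s} {t:12.5g} {f:12.5g} {abs(f - t) / abs(t):10.2e}")
print(f"\njoint objective (residual SSE) at the solution: "
      f"{result.joint_objective:.3e}")
print("relative fit errors per biomarker (fraction):",
      {k: round(v, 6) for k, v in result.relative_errors.items()})
print("\nWith noiseless, well-spread observations the fit closes the "
      "generate-and-refit\nloop to near machine precision; residuals and "
      "relative errors are ~0.")
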