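"""Personalized optimal dosing schedule for one subject.

Solves the Pontryagin optimality system by forward-backward sweep for a
78-week donanemab course starting at age 60, and compares terminal
amyloid and cognition against the untreated trajectory.
"""

import numpy as np

from adcascade import (OCConfig, SubjectParameters, forward_backward_sweep,
                       get_drug, simulate)
from adcascade.cohort import SLOW_PROGRESSION_STATS

params = SubjectParameters.from_dict(
    {k: v[0] for k, v in SLOW_PROGRESSION_STATS.items()} | {"T0": 50.0})
drug = get_drug("donanemab")
cfg = OCConfig(u_max=drug.u_max_per_year, T1=60.0, T2=61.5)

sol = forward_backward_sweep(params, cfg)
untreated = simulate(params, params.T0, cfg.T2, step=cfg.step)

print(f"sweep converged in {sol.iterations} iterations "
      f"(objective J = {sol.objective:.2f})")
print("weeks on treatment | clearance rate u (/year)")
for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
    k = int(frac * (len(sol.u) - 1))
    weeks = (sol.times[k] - cfg.T1) * 52
    print(f"{weeks:18.0f} | {sol.u[k]:.4f}  (u_max = {cfg.u_max:.4f})")

pct = (sol.states.C[-1] - untreated.C[-1]) / untreated.C[-1] * 100
print(f"\nterminal amyloid: {sol.states.Abeta[-1]:.1f} treated vs "
      f"{untreated.Abeta[-1]:.1f} untreated")
print(f"terminal cognition: {sol.states.C[-1]:.3f} treated vs "
      f"{untreated.C[-1]:.3f} untreated  ({-pct:.3f}% less decline)")
print("\nThe optimal schedule ramps up as the amyloid-dependent "
      "side-effect weight decays,\nreaching the clearance ceiling late "
      "in the course -- the dose-titration pattern\nused in the actual "
      "trials.")
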