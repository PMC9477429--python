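"""Simulate the five-biomarker cascade for an average AD-group subject.

Builds a subject from the published AD-group mean parameters, integrates
the untreated cascade from the reference age (50) to 90, and checks the
amyloid component against its closed-form logistic solution.
"""

import numpy as np

from adcascade import SubjectParameters, analytic_abeta, simulate
from adcascade.reference import GROUP_STATS

params = SubjectParameters.from_dict(
    {k: v[0] for k, v in GROUP_STATS["AD"].items()} | {"T0": 50.0})

traj = simulate(params, 50.0, 90.0, step=0.01)
closed = analytic_abeta(traj.times, params)

print("age   Abeta    taup    tauo      N       C")
for age in (50, 60, 70, 80, 90):
    row = traj.states[np.searchsorted(traj.times, age)]
    print(f"{age:3d} {row[0]:8.2f} {row[1]:7.2f} {row[2]:7.2f}"
          f" {row[3]:7.3f} {row[4]:7.2f}")

err = np.max(np.abs(traj.Abeta - closed) / closed)
print(f"\nmax relative deviation of RK4 amyloid from the closed form: "
      f"{err:.2e}")
print("Amyloid saturates toward its carrying capacity (259.4); tau, "
      "neurodegeneration\nand cognition follow and saturate in cascade "
      "order -- an average AD-group subject\nis already near-plateaued "
      "in cognition by age 60.")
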