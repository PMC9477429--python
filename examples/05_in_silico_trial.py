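"""A 12-arm in-silico trial over a seeded synthetic responder cohort.

Runs every drug x start-age x duration arm over ten slow-progression
subjects and prints the arm medians of the cognitive decline reduction
at end of treatment (positive = less decline than untreated).
"""

from adcascade import generate_cohort, get_drug, run_trial
from adcascade.cohort import slow_progression_spec

cohort = generate_cohort(slow_progression_spec(n=10, seed=1))
subjects = list(zip(cohort.subject_ids, cohort.subjects))
drugs = [get_drug(n) for n in ("aducanumab-low", "aducanumab-high",
                               "donanemab")]

reports = run_trial(subjects, drugs)

print("duration  start  drug              median decline reduction")
for r in reports:
    n_nr = int(r.table["nr"].sum())
    print(f"{r.arm.duration_years:7.2g}y  {r.arm.start_age:5.0f}  "
          f"{r.arm.drug.name:16s}  {r.median_decline_reduction:10.4f}%"
          f"   ({n_nr} NR)")

print("\nStronger clearance (donanemab > high > low dose), longer "
      "treatment (10y > 78w)\nand earlier start (60 > 70) each increase "
      "the median benefit -- the ordering\npattern of the published "
      "per-group tables.")
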