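"""In-silico treatment trials: untreated versus optimally dosed cohorts.

For each subject in an arm the untreated cascade is simulated from the
reference age through the end of treatment, the personalized optimal
control problem is solved on the treatment window, and the effect is
summarized as the cognitive percentage change at the end of treatment,

    100 * (C_treated(T2) - C_untreated(T2)) / C_untreated(T2),

negative when treatment slows decline.  Report tables follow the
convention of quoting the magnitude of decline reduction (the negated
change), so positive entries mean less cognitive decline.  A subject
whose absolute percentage change is below 1e-7 is classified as a
non-responder ("NR") and contributes zero to the arm median.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .control import ControlSolution, OCConfig, forward_backward_sweep
from .drugs import DrugDefinition
from .model import SubjectParameters, simulate

__all__ = ["NR_THRESHOLD", "TrialArm", "TrialReport",
           "cognitive_percent_change", "run_arm", "run_trial",
           "write_report", "read_report"]

logger = logging.getLogger(__name__)

#: "No response": absolute cognitive percentage change below this value.
NR_THRESHOLD = 1e-7

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class TrialArm:
    """One drug/start-age/duration combination with its solver settings."""

    drug: DrugDefinition
    start_age: float            # years; the study designs use 60 and 70
    duration_years: float       # 78 weeks = 1.5 years, or 10 years
    oc_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_years <= 0:
            raise ValueError("duration must be > 0")

    @property
    def label(self) -> str:
        return (f"{self.drug.name}@{self.start_age:g}"
                f"/{self.duration_years:g}y")

    def config(self) -> OCConfig:
        return OCConfig(u_max=self.drug.u_max_per_year,
                        T1=self.start_age,
                        T2=self.start_age + self.duration_years,
                        **self.oc_overrides)


def cognitive_percent_change(C_treated: float, C_untreated: float) -> float:
    """Signed percentage change of end-of-treatment cognition.

    Requires untreated cognition > 0; a zero denominator means the
    change is undefined and the caller should classify the subject as a
    non-responder (NaN is returned and a warning logged).
    """
    if C_untreated < 0:
        raise ValueError("C_untreated must be >= 0")
    if C_untreated == 0:
        logger.warning("untreated cognition is zero; percentage change "
                       "undefined, treating as no response")
        return math.nan
    return (C_treated - C_untreated) / C_untreated * 100.0


@dataclass
class TrialReport:
    """Per-subject and aggregate results for one arm.

    ``table`` has one row per subject with the signed percent change,
    the decline reduction (its negation), the maximum reduction over the
    treatment window, the NR flag and sweep diagnostics.  The aggregate
    ``median_decline_reduction`` is taken over all converged subjects
    with NR subjects contributing zero.
    """

    arm: TrialArm
    table: pd.DataFrame
    median_decline_reduction: float
    n_nonconverged: int


def _treat_subject(params: SubjectParameters, arm: TrialArm,
                   ) -> tuple[dict, ControlSolution]:
    cfg = arm.config()
    untreated = simulate(params, params.T0, cfg.T2, step=cfg.step)
    sol = forward_backward_sweep(params, cfg)
    c_untr = float(untreated.C[-1])
    c_trt = float(sol.states.C[-1])
    pct = cognitive_percent_change(c_trt, c_untr)
    nr = math.isnan(pct) or abs(pct) < NR_THRESHOLD
    if math.isnan(pct):
        pct = 0.0
    # maximum effect over the treatment window (largest decline reduction)
    c0_grid = untreated.value_at(sol.times, "C")
    with np.errstate(divide="ignore", invalid="ignore"):
        course = np.where(c0_grid > 0,
                          -(sol.states.C - c0_grid) / c0_grid * 100.0, 0.0)
    row = {
        "percent_change": 0.0 if nr else pct,
        "decline_reduction": 0.0 if nr else -pct,
        "max_decline_reduction": float(np.max(course)),
        "nr": bool(nr),
        "objective": sol.objective,
        "iterations": sol.iterations,
        "converged": sol.converged,
    }
    return row, sol


def run_arm(cohort: Sequence[SubjectParameters] |
            Sequence[tuple[str, SubjectParameters]],
            arm: TrialArm) -> TrialReport:
    """Run one arm over a cohort and aggregate the median effect.

    ``cohort`` is a sequence of parameter sets or (id, parameters)
    pairs.  Non-converged subjects are flagged and excluded from the
    median but counted in the report.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    rows = []
    for i, entry in enumerate(cohort):
        if isinstance(entry, SubjectParameters):
            sid, params = f"S{i + 1}", entry
        else:
            sid, params = entry
        row, _ = _treat_subject(params, arm)
        row["subject_id"] = sid
        rows.append(row)
    table = pd.DataFrame(rows)[["subject_id", "percent_change",
                                "decline_reduction",
                                "max_decline_reduction", "nr", "objective",
                                "iterations", "converged"]]
    ok = table[table["converged"]]
    median = float(ok["decline_reduction"].median()) if len(ok) else math.nan
    n_bad = int((~table["converged"]).sum())
    if n_bad:
        logger.warning("arm %s: %d subject(s) did not converge and are "
                       "excluded from the median", arm.label, n_bad)
    return TrialReport(arm, table, median, n_bad)


def run_trial(cohort, drugs: Sequence[DrugDefinition],
              start_ages: Sequence[float] = (60.0, 70.0),
              durations_years: Sequence[float] = (78 / 52, 10.0),
              oc_overrides: dict | None = None) -> list[TrialReport]:
    """All drug x start-age x duration arms over one cohort."""
    reports = []
    for duration in durations_years:
        for age in start_ages:
            for drug in drugs:
                arm = TrialArm(drug, age, duration,
                               dict(oc_overrides or {}))
                reports.append(run_arm(cohort, arm))
    return reports


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _tidy(reports: Sequence[TrialReport]) -> pd.DataFrame:
    frames = []
    for r in reports:
        t = r.table.copy()
        t.insert(1, "drug", r.arm.drug.name)
        t.insert(2, "start_age", r.arm.start_age)
        t.insert(3, "duration_years", r.arm.duration_years)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def write_report(reports: TrialReport | Sequence[TrialReport], path,
                 layout: str = "tidy") -> None:
    """Write one or more arm reports as delimited text.

    ``tidy`` emits one row per subject x arm.  The ``table`` layouts
    (aliases ``table2``/``table3``/``table4``) pivot arms into columns
    (start age x drug), render non-responders literally as ``NR``, and
    append the arm medians as a final row.
    """
    if isinstance(reports, TrialReport):
        reports = [reports]
    if not reports:
        raise ValueError("no reports to write")
    if layout == "tidy":
        _tidy(reports).to_csv(path, index=False)
        return
    if layout not in ("table", "table2", "table3", "table4"):
        raise ValueError(f"unknown layout {layout!r}")
    tidy = _tidy(reports)
    if tidy.empty:
        warnings.warn("empty trial report; writing header only")
        pd.DataFrame(columns=["Subject"]).to_csv(path, index=False)
        return
    cells = tidy.copy()
    cells["cell"] = [
        "NR" if nr else repr(v)
        for nr, v in zip(cells["nr"], cells["decline_reduction"])]
    cells["column"] = [
        f"age{a:g}|{d}|{y:g}y" for a, d, y in
        zip(cells["start_age"], cells["drug"], cells["duration_years"])]
    wide = cells.pivot(index="subject_id", columns="column", values="cell")
    wide.index.name = "Subject"
    medians = {}
    for r in reports:
        col = (f"age{r.arm.start_age:g}|{r.arm.drug.name}"
               f"|{r.arm.duration_years:g}y")
        medians[col] = repr(r.median_decline_reduction)
    wide.loc["Median"] = pd.Series(medians)
    wide.to_csv(path)


def read_report(path) -> pd.DataFrame:
    """Round-trip reader for the tidy layout."""
    return pd.read_csv(path)
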