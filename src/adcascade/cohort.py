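"""Synthetic longitudinal cohorts with known ground-truth parameters.

The generator emulates the sampling design of a multicenter natural
history study of Alzheimer's biomarkers: CSF measures (amyloid-beta 42,
phosphorylated tau, total tau) every two years over a ten-year
follow-up, volumetric neurodegeneration measures yearly, and cognitive
testing every six months, with baseline ages drawn uniformly over
54-85 years.  Subject parameters are drawn independently per parameter
from normal distributions with the published per-group means and
standard deviations, floored at a small positive value (rates must stay
nonnegative for the cascade to be well-posed) and with initial
conditions capped at their sampled carrying capacities.

Observations are the noiseless model trajectory sampled at the visit
schedule, optionally perturbed by multiplicative Gaussian noise with a
per-biomarker coefficient of variation.  Because the ground truth is
known, the cohorts support parameter-recovery scoring of the
calibration pipeline and fully reproducible in-silico trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import LongitudinalRecord
from .model import STATE_NAMES, SubjectParameters, simulate
from .reference import GROUP_SIZES, GROUP_STATS, PARAM_ORDER

__all__ = ["CohortSpec", "Cohort", "sample_parameters", "generate_records",
           "generate_cohort", "SLOW_PROGRESSION_STATS",
           "slow_progression_spec"]

_PARAM_FLOOR = 1e-6

#: (visit interval, follow-up horizon) in years per biomarker
DEFAULT_SCHEDULES = {
    "Abeta": (2.0, 10.0),
    "taup": (2.0, 10.0),
    "tauo": (2.0, 10.0),
    "N": (1.0, 10.0),
    "C": (0.5, 10.0),
}

#: multiplicative noise, coefficient of variation per biomarker
DEFAULT_CVS = {"Abeta": 0.05, "taup": 0.05, "tauo": 0.05, "N": 0.01,
               "C": 0.10}

_IC_CAP = {"A0": "K_Abeta", "taup0": "K_taup", "N0": "K_N", "C0": "K_C"}


@dataclass
class CohortSpec:
    """Study design: group sizes, parameter statistics, visit schedules,
    baseline-age range, noise model, and the random seed."""

    n_subjects: dict[str, int] = field(
        default_factory=lambda: dict(GROUP_SIZES))
    group_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(s) for g, s in GROUP_STATS.items()})
    schedules: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES))
    baseline_age_range: tuple[float, float] = (54.0, 85.0)
    cvs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CVS))
    seed: int = 0
    sim_step: float = 0.01
    T0: float = 50.0

    def __post_init__(self) -> None:
        for g, n in self.n_subjects.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have n >= 1")
            if g not in self.group_stats:
                raise ValueError(f"no statistics for group {g!r}")
        for g, stats in self.group_stats.items():
            for p, (_, s) in stats.items():
                if s < 0:
                    raise ValueError(f"{g}/{p}: std must be >= 0")
        for bm, (interval, horizon) in self.schedules.items():
            if bm not in STATE_NAMES:
                raise ValueError(f"unknown biomarker {bm!r} in schedule")
            if int(np.floor(horizon / interval)) + 1 < 3:
                raise ValueError(
                    f"{bm} schedule yields fewer than 3 visits; the "
                    "inclusion rule requires at least 3 per biomarker")
        for bm, cv in self.cvs.items():
            if cv < 0:
                raise ValueError(f"{bm}: cv must be >= 0")
        lo, hi = self.baseline_age_range
        if not self.T0 <= lo <= hi:
            raise ValueError("baseline ages must satisfy T0 <= lo <= hi")

    def visit_offsets(self, biomarker: str) -> np.ndarray:
        interval, horizon = self.schedules[biomarker]
        k = int(np.floor(horizon / interval + 1e-9))
        return interval * np.arange(k + 1)


def sample_parameters(spec: CohortSpec, group: str,
                      rng: np.random.Generator | None = None
                      ) -> list[SubjectParameters]:
    """Draw one parameter set per subject of ``group``.

    Each of the 16 parameters is an independent normal draw with the
    group's mean/std, floored at 1e-6; initial conditions are then
    capped at their sampled capacities.  Carrying capacities are floored
    at 5% of their group mean instead: several published stds exceed
    their means, and a capacity far below the biomarker's observable
    scale is biologically meaningless while making the logistic terms
    artificially stiff.  Deterministic for a fixed seed.
    """
    if group not in spec.group_stats:
        raise ValueError(f"no statistics for group {group!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    stats = spec.group_stats[group]
    caps = set(_IC_CAP.values())
    out = []
    for _ in range(spec.n_subjects.get(group, 0)):
        d: dict[str, float] = {}
        for name in PARAM_ORDER:
            mean, std = stats[name]
            floor = max(_PARAM_FLOOR,
                        0.05 * mean) if name in caps else _PARAM_FLOOR
            d[name] = max(float(rng.normal(mean, std)), floor)
        for ic, cap in _IC_CAP.items():
            d[ic] = min(d[ic], d[cap])
        d["T0"] = spec.T0
        out.append(SubjectParameters.from_dict(d))
    return out


def generate_records(subjects: list[SubjectParameters], spec: CohortSpec,
                     rng: np.random.Generator | None = None,
                     ids: list[str] | None = None,
                     baseline_ages: np.ndarray | None = None
                     ) -> tuple[list[LongitudinalRecord], np.ndarray]:
    """Sample each subject's untreated trajectory at the visit schedule.

    Subjects are integrated from the reference age T0; visits start at a
    baseline age drawn uniformly from the spec's range.  Returns the
    records and the baseline ages used.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if ids is None:
        ids = [f"S{i + 1}" for i in range(len(subjects))]
    if baseline_ages is None:
        lo, hi = spec.baseline_age_range
        baseline_ages = rng.uniform(lo, hi, size=len(subjects))
    baseline_ages = np.asarray(baseline_ages, float)
    records = []
    for sid, params, b0 in zip(ids, subjects, baseline_ages):
        horizon = max(h for _, h in spec.schedules.values())
        traj = simulate(params, params.T0, b0 + horizon, step=spec.sim_step)
        series = {}
        for bm in spec.schedules:
            ages = b0 + spec.visit_offsets(bm)
            vals = np.interp(ages, traj.times, traj.series(bm))
            cv = spec.cvs.get(bm, 0.0)
            if cv > 0:
                vals = vals * (1.0 + cv * rng.standard_normal(vals.size))
            series[bm] = (ages, np.maximum(vals, 1e-9))
        records.append(LongitudinalRecord(sid, series))
    return records, baseline_ages


@dataclass
class Cohort:
    """A generated cohort: per-subject truth, group labels, and records."""

    spec: CohortSpec
    subject_ids: list[str]
    groups: list[str]
    subjects: list[SubjectParameters]
    baseline_ages: np.ndarray
    records: list[LongitudinalRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for sid, grp, params, b0 in zip(self.subject_ids, self.groups,
                                        self.subjects, self.baseline_ages):
            row = {"subject_id": sid, "group": grp, "baseline_age": b0}
            row.update(params.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def records_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.records],
                         ignore_index=True)


#: Slow-progression ("responder") parameter statistics for validation
#: studies.  Sampling the published group means and standard deviations
#: independently yields cohorts whose tau, neurodegeneration and
#: cognition series saturate before or during the visit window (the
#: published per-group means combine into faster joint dynamics than any
#: real fitted subject, since parameter correlations are not published).
#: Saturated series carry no information about their rates -- the
#: calibration module flags them as unidentifiable -- and such subjects
#: are non-responders under any clearance schedule.  This stats set
#: keeps every biomarker in its dynamic phase through roughly ages
#: 54-80 (10% relative spread per parameter), which is the regime where
#: parameter-recovery and treatment-response properties are
#: informative.  It is a validation instrument, not an empirical cohort.
SLOW_PROGRESSION_STATS: dict[str, tuple[float, float]] = {
    "A0": (36.0, 3.6),
    "taup0": (10.0, 1.0),
    "tauo0": (30.0, 3.0),
    "N0": (0.30, 0.03),
    "C0": (5.0, 0.5),
    "lambda_Abeta": (0.18, 0.018),
    "K_Abeta": (260.0, 26.0),
    "lambda_tau": (0.02, 0.002),
    "K_taup": (123.0, 12.3),
    "lambda_tauo": (1.0, 0.1),
    "lambda_N_tauo": (3.75e-4, 3.75e-5),
    "lambda_N_taup": (2.0e-3, 2.0e-4),
    "K_N": (1.0, 0.05),
    "lambda_CN": (1.0, 0.1),
    "lambda_Ctau": (0.05, 0.005),
    "K_C": (170.0, 17.0),
}


def slow_progression_spec(n: int = 10, seed: int = 0,
                          noiseless: bool = False,
                          baseline_age_range: tuple[float, float] = (54.0,
                                                                     60.0)
                          ) -> CohortSpec:
    """A seeded slow-progression cohort spec for validation studies.

    ``noiseless`` zeroes every observation CV (exact model samples);
    the default baseline window keeps all visits inside the dynamic
    phase of every biomarker ("well-spread" observations).
    """
    cvs = ({bm: 0.0 for bm in DEFAULT_CVS} if noiseless
           else dict(DEFAULT_CVS))
    return CohortSpec(n_subjects={"SLOW": n},
                      group_stats={"SLOW": dict(SLOW_PROGRESSION_STATS)},
                      cvs=cvs, seed=seed,
                      baseline_age_range=baseline_age_range)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate all groups of the spec with one seeded random stream."""
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    groups: list[str] = []
    subjects: list[SubjectParameters] = []
    ages_all: list[np.ndarray] = []
    records: list[LongitudinalRecord] = []
    for group in spec.n_subjects:
        params = sample_parameters(spec, group, rng)
        gids = [f"{group}{i + 1}" for i in range(len(params))]
        recs, ages = generate_records(params, spec, rng, ids=gids)
        ids.extend(gids)
        groups.extend([group] * len(params))
        subjects.extend(params)
        ages_all.append(ages)
        records.extend(recs)
    baseline = (np.concatenate(ages_all) if ages_all
                else np.empty(0))
    return Cohort(spec, ids, groups, subjects, baseline, records)
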