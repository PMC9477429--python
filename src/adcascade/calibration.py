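"""Per-subject parameter estimation from longitudinal biomarker data.

The full problem is a nonlinear least-squares fit of all rates,
capacities and initial conditions of the cascade model to one subject's
observed series,

    min_p  sum_i || x(t_i; p) - x_obs(t_i) ||^2,

summing only over the biomarkers and visits actually observed.  Because
the objective is badly non-convex in the 16-dimensional parameter space,
the fit proceeds sequentially, equation by equation, following the
cascade order (amyloid -> p-tau, age-related tau -> neurodegeneration
-> cognition): each stage fits only its own parameters and initial
condition with all upstream quantities frozen, and the resulting
estimate warm-starts a final joint refinement over everything.

Subjects must contribute at least three longitudinal datapoints per
fitted biomarker; series failing the rule raise :class:`ExclusionError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (IC_NAMES, RATE_PARAM_NAMES, STATE_NAMES,
                    IntegrationError, SubjectParameters, _grid, _rk4_forward)
from .reference import rate_upper_bounds

__all__ = [
    "MIN_POINTS",
    "ExclusionError",
    "LongitudinalRecord",
    "StageFit",
    "CalibrationResult",
    "fit_abeta",
    "fit_stage",
    "sequential_fit",
    "fit_joint",
    "calibrate",
    "relative_error",
    "joint_sse",
    "read_records",
    "write_records",
    "results_frame",
    "cohort_summary",
]

#: Minimum longitudinal datapoints per fitted biomarker (inclusion rule).
MIN_POINTS = 3

_DEFAULT_T0 = 50.0
_FLAT_TOL = 1e-8


class ExclusionError(ValueError):
    """A subject fails an inclusion rule; carries the explicit reason."""


@dataclass
class LongitudinalRecord:
    """Observed (age, value) pairs per biomarker for one subject.

    Series are sorted by age on construction, so datapoint order in the
    input never affects a fit.  Biomarker names must come from the model
    vocabulary ``{Abeta, taup, tauo, N, C}``.
    """

    subject_id: str
    series: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (ages, values) in self.series.items():
            if name not in STATE_NAMES:
                raise ValueError(f"unknown biomarker {name!r}; "
                                 f"expected one of {STATE_NAMES}")
            ages = np.asarray(ages, float)
            values = np.asarray(values, float)
            if ages.shape != values.shape or ages.ndim != 1:
                raise ValueError(f"{name}: ages and values must be 1-D and "
                                 "equally long")
            if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(values))):
                raise ValueError(f"{name}: non-finite entries")
            order = np.argsort(ages, kind="stable")
            ages, values = ages[order], values[order]
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"{name}: duplicate visit ages")
            clean[name] = (ages, values)
        self.series = clean

    def has(self, biomarker: str) -> bool:
        return biomarker in self.series

    def n_points(self, biomarker: str) -> int:
        return self.series[biomarker][0].size if self.has(biomarker) else 0

    def ages(self, biomarker: str) -> np.ndarray:
        return self.series[biomarker][0]

    def values(self, biomarker: str) -> np.ndarray:
        return self.series[biomarker][1]

    def require(self, biomarker: str) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_points(biomarker)
        if n < MIN_POINTS:
            raise ExclusionError(
                f"subject {self.subject_id!r}: {n} {biomarker} datapoint(s), "
                f"inclusion requires at least {MIN_POINTS}")
        return self.series[biomarker]

    def max_age(self) -> float:
        return max(float(a[-1]) for a, _ in self.series.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (ages, values) in self.series.items():
            for a, v in zip(ages, values):
                rows.append((self.subject_id, name, a, v))
        return pd.DataFrame(rows,
                            columns=["subject_id", "biomarker", "age", "value"])


def read_records(path) -> list[LongitudinalRecord]:
    """Read tidy delimited text (subject_id, biomarker, age, value)."""
    df = pd.read_csv(path)
    missing = {"subject_id", "biomarker", "age", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"input is missing columns {sorted(missing)}")
    out = []
    for sid, g in df.groupby("subject_id", sort=False):
        series = {str(bm): (sg["age"].to_numpy(), sg["value"].to_numpy())
                  for bm, sg in g.groupby("biomarker", sort=False)}
        out.append(LongitudinalRecord(str(sid), series))
    return out


def write_records(records: Sequence[LongitudinalRecord], path) -> None:
    pd.concat([r.to_frame() for r in records],
              ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Forward model plumbing
# ---------------------------------------------------------------------------

def _pack(params: SubjectParameters) -> np.ndarray:
    return np.array([getattr(params, n) for n in RATE_PARAM_NAMES]
                    + [getattr(params, n) for n in IC_NAMES], float)


def _unpack(x: np.ndarray, T0: float) -> SubjectParameters:
    d = dict(zip(RATE_PARAM_NAMES, x[:11]))
    d.update(zip(IC_NAMES, x[11:16]))
    # clip initial conditions to their fitted capacities (round-off guard)
    for ic, cap in (("A0", "K_Abeta"), ("taup0", "K_taup"),
                    ("N0", "K_N"), ("C0", "K_C")):
        d[ic] = min(max(d[ic], 0.0), d[cap])
    d["T0"] = T0
    return SubjectParameters(**d)


def _predict(x: np.ndarray, T0: float, targets: Mapping[str, np.ndarray],
             step: float) -> dict[str, np.ndarray]:
    """Model values at observed ages for a packed parameter vector."""
    t_end = max(float(a[-1]) for a in targets.values())
    n, h = _grid(T0, t_end, step)
    y0 = np.array(x[11:16], float)
    states, status, bad = _rk4_forward(y0, T0, h, n, np.array(x[:11], float),
                                       np.zeros(n + 1))
    if status:
        raise IntegrationError("integration failed during calibration",
                               time=T0 + bad * h)
    times = T0 + h * np.arange(n + 1)
    return {bm: np.interp(a, times, states[:, STATE_NAMES.index(bm)])
            for bm, a in targets.items()}


def joint_sse(params: SubjectParameters, record: LongitudinalRecord,
              step: float = 0.01,
              weights: Mapping[str, float] | None = None) -> float:
    """The joint least-squares objective at ``params`` (lower is better)."""
    targets = {bm: record.ages(bm) for bm in STATE_NAMES if record.has(bm)}
    pred = _predict(_pack(params), params.T0, targets, step)
    total = 0.0
    for bm, ages in targets.items():
        w = 1.0 if weights is None else float(weights.get(bm, 1.0))
        r = pred[bm] - record.values(bm)
        total += w * float(r @ r)
    return total


def relative_error(model_values, observed, form: str = "mad") -> float:
    """Mean relative deviation between model and observed series.

    ``form="mad"`` is the mean absolute relative deviation
    (1/n) sum |x_i - obs_i| / |obs_i|; ``form="rmsre"`` is the root of the
    mean squared relative error.  Returned as a fraction (multiply by 100
    for percent).
    """
    m = np.asarray(model_values, float)
    o = np.asarray(observed, float)
    if m.shape != o.shape or m.ndim != 1 or m.size < 1:
        raise ValueError("series must be 1-D, non-empty, equal length")
    if np.any(o == 0):
        raise ValueError("observed values must be nonzero")
    rel = (m - o) / o
    if form == "mad":
        return float(np.mean(np.abs(rel)))
    if form == "rmsre":
        return float(np.sqrt(np.mean(rel * rel)))
    raise ValueError("form must be 'mad' or 'rmsre'")


# ---------------------------------------------------------------------------
# Bounds
# ---------------------------------------------------------------------------

def default_bounds(record: LongitudinalRecord) -> dict[str, tuple[float, float]]:
    """Default parameter box: rates in [0, 10x largest group mean],
    capacities in [max observed, 10x max observed], initial conditions in
    [0, capacity upper bound]."""
    rub = rate_upper_bounds()
    b: dict[str, tuple[float, float]] = {n: (0.0, rub[n]) for n in rub}

    def cap(bm: str, fallback: float) -> tuple[float, float]:
        if record.has(bm):
            hi = float(np.max(record.values(bm)))
            hi = max(hi, 1e-6)
            return (hi, 10.0 * hi)
        return (1e-6, fallback)

    b["K_Abeta"] = cap("Abeta", 1e4)
    b["K_taup"] = cap("taup", 1e4)
    b["K_N"] = cap("N", 1e2)
    b["K_C"] = cap("C", 1e4)
    b["A0"] = (1e-6, b["K_Abeta"][1])
    b["taup0"] = (0.0, b["K_taup"][1])
    b["tauo0"] = (0.0, 10.0 * max(1e-6, float(np.max(record.values("tauo")))
                                  if record.has("tauo") else 1.0))
    b["N0"] = (0.0, b["K_N"][1])
    b["C0"] = (0.0, b["K_C"][1])
    return b


def _ls(fun, x0, lo, hi, max_nfev=None):
    x0 = np.clip(np.asarray(x0, float), lo, hi)
    return least_squares(fun, x0, bounds=(lo, hi), method="trf",
                         x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14,
                         max_nfev=max_nfev)


# ---------------------------------------------------------------------------
# Stage fits (equation-by-equation warm start)
# ---------------------------------------------------------------------------

@dataclass
class StageFit:
    """Result of one equation's fit: parameter values, residual SSE,
    and an identifiability diagnostic for degenerate (flat/saturated)
    data."""

    stage: str
    values: dict[str, float]
    sse: float
    identifiable: bool = True
    message: str = ""


def _is_flat(values: np.ndarray) -> bool:
    return float(np.ptp(values)) <= _FLAT_TOL * max(1.0,
                                                    float(np.max(np.abs(values))))


def fit_abeta(record: LongitudinalRecord,
              bounds: Mapping[str, tuple[float, float]] | None = None,
              T0: float = _DEFAULT_T0) -> StageFit:
    """Fit (lambda_Abeta, K_Abeta, A0) to the amyloid series using the
    closed-form logistic solution (no integration needed)."""
    ages, y = record.require("Abeta")
    b = bounds or default_bounds(record)
    lo = np.array([b["lambda_Abeta"][0], b["K_Abeta"][0], b["A0"][0]])
    hi = np.array([b["lambda_Abeta"][1], b["K_Abeta"][1], b["A0"][1]])

    if _is_flat(y):
        v = float(np.mean(y))
        a0 = min(max(v, lo[2]), hi[2])
        vals = {"lambda_Abeta": lo[0], "K_Abeta": max(lo[1], v), "A0": a0}
        sse = float(np.sum((a0 - y) ** 2))
        return StageFit("Abeta", vals, sse, identifiable=False,
                        message="flat amyloid series; growth rate "
                                "unidentifiable, zero-growth fit returned")

    def model(x):
        lam, K, A0 = x
        A0 = max(A0, 1e-12)
        c1 = K / A0 - 1.0
        return K / (c1 * np.exp(-lam * (ages - T0)) + 1.0)

    def resid(x):
        return model(x) - y

    ymax = float(np.max(y))
    Kg = min(max(1.2 * ymax, lo[1]), hi[1])
    with np.errstate(divide="ignore"):
        z = np.log(np.maximum(Kg / y - 1.0, 1e-12))
    m, b0 = np.polyfit(ages, z, 1)
    lam_g = min(max(-m, 1e-4), hi[0])
    A0_g = min(max(Kg / (math.exp(b0 + m * T0) + 1.0), lo[2]), hi[2])

    best = None
    for scale in (1.0, 0.3, 3.0):
        res = _ls(resid, [lam_g * scale, Kg, A0_g], lo, hi)
        if best is None or res.cost < best.cost:
            best = res
    vals = dict(zip(("lambda_Abeta", "K_Abeta", "A0"), best.x))
    return StageFit("Abeta", vals, 2.0 * best.cost)


#: parameters each downstream stage owns (plus its initial condition)
STAGE_PARAMS = {
    "taup": ("lambda_tau", "K_taup", "taup0"),
    "tauo": ("lambda_tauo", "tauo0"),
    "N": ("lambda_N_tauo", "lambda_N_taup", "K_N", "N0"),
    "C": ("lambda_CN", "K_C", "C0"),
}

_UPSTREAM = {
    "taup": ("lambda_Abeta", "K_Abeta", "A0"),
    "tauo": (),
    "N": ("lambda_Abeta", "K_Abeta", "A0", "lambda_tau", "K_taup", "taup0",
          "lambda_tauo", "tauo0"),
    "C": ("lambda_Abeta", "K_Abeta", "A0", "lambda_tau", "K_taup", "taup0",
          "lambda_tauo", "tauo0", "lambda_N_tauo", "lambda_N_taup", "K_N",
          "N0"),
}

_NEUTRAL = {"lambda_Abeta": 0.0, "K_Abeta": 1.0, "lambda_tau": 0.0,
            "K_taup": 1.0, "lambda_tauo": 0.0, "lambda_N_tauo": 0.0,
            "lambda_N_taup": 0.0, "K_N": 1.0, "lambda_CN": 0.0,
            "lambda_Ctau": 0.0, "K_C": 1.0, "A0": 0.0, "taup0": 0.0,
            "tauo0": 0.0, "N0": 0.0, "C0": 0.0}


def fit_stage(stage: str, record: LongitudinalRecord,
              fixed: Mapping[str, float],
              bounds: Mapping[str, tuple[float, float]] | None = None,
              step: float = 0.01, T0: float = _DEFAULT_T0) -> StageFit:
    """Fit one downstream equation's parameters with upstream ones frozen.

    ``stage`` is one of ``taup``, ``tauo``, ``N``, ``C``; ``fixed`` must
    contain every upstream parameter (from earlier stages).  The ``C``
    stage fits only (lambda_CN, K_C, C0); the tau-coupling rate
    lambda_Ctau is taken from ``fixed`` if present (default 0) and left
    to the joint refinement.
    """
    if stage not in STAGE_PARAMS:
        raise ValueError(f"unknown stage {stage!r}")
    missing = [k for k in _UPSTREAM[stage] if k not in fixed]
    if missing:
        raise ValueError(f"stage {stage!r} requires upstream parameters "
                         f"{missing}")
    ages, y = record.require(stage)
    names = STAGE_PARAMS[stage]
    b = bounds or default_bounds(record)
    lo = np.array([b[n][0] for n in names])
    hi = np.array([b[n][1] for n in names])

    if stage == "tauo":
        # exact linear closed form: tauo(t) = tauo0 + lambda_tauo*(t - T0)
        if _is_flat(y):
            vals = {"lambda_tauo": 0.0,
                    "tauo0": min(max(float(np.mean(y)), lo[1]), hi[1])}
            sse = float(np.sum((vals["tauo0"] - y) ** 2))
            return StageFit(stage, vals, sse, identifiable=False,
                            message="flat tauo series; rate unidentifiable")
        slope, icpt = np.polyfit(ages - T0, y, 1)

        def resid(x):
            return x[1] + x[0] * (ages - T0) - y

        res = _ls(resid, [slope, icpt], lo, hi)
        vals = dict(zip(names, res.x))
        return StageFit(stage, vals, 2.0 * res.cost)

    if _is_flat(y):
        v = float(np.mean(y))
        vals = {}
        for n in names:
            if n.startswith("lambda"):
                vals[n] = 0.0
            elif n.startswith("K"):
                vals[n] = min(max(v, b[n][0]), b[n][1])
            else:
                vals[n] = min(max(v, b[n][0]), b[n][1])
        sse = float(np.sum((vals[names[-1]] - y) ** 2))
        return StageFit(stage, vals, sse, identifiable=False,
                        message=f"flat/saturated {stage} series; rates "
                                "unidentifiable, zero-rate fit returned")

    base = {**_NEUTRAL, **{k: float(v) for k, v in fixed.items()}}

    def resid(x):
        d = dict(base)
        d.update(zip(names, x))
        vec = np.array([d[n] for n in RATE_PARAM_NAMES]
                       + [d[n] for n in IC_NAMES], float)
        pred = _predict(vec, T0, {stage: ages}, step)[stage]
        return pred - y

    x0 = _stage_guess(stage, names, ages, y, base, b, step, T0)
    best = None
    for scale in (1.0, 0.3, 3.0):
        guess = [v * scale if n.startswith("lambda") else v
                 for n, v in zip(names, x0)]
        res = _ls(resid, guess, lo, hi)
        if best is None or res.cost < best.cost:
            best = res
    vals = dict(zip(names, best.x))
    return StageFit(stage, vals, 2.0 * best.cost)


def _stage_guess(stage, names, ages, y, base, b, step, T0):
    """Heuristic initial guesses from first-visit slopes and the
    upstream trajectory evaluated at the first visit."""
    up_vec = np.array([base[n] for n in RATE_PARAM_NAMES]
                      + [base[n] for n in IC_NAMES], float)
    up = _predict(up_vec, T0, {"Abeta": ages, "taup": ages, "tauo": ages,
                               "N": ages}, step)
    s0 = (y[1] - y[0]) / (ages[1] - ages[0])
    s0 = max(s0, 1e-6)
    if stage == "taup":
        Kg = min(max(1.2 * float(np.max(y)), b["K_taup"][0]), b["K_taup"][1])
        drive = max(up["Abeta"][0], 1e-6) * max(1.0 - y[0] / Kg, 0.05)
        lam = min(max(s0 / drive, 1e-4), b["lambda_tau"][1])
        return [lam, Kg, max(y[0], 1e-6)]
    if stage == "N":
        Kg = min(max(1.05 * float(np.max(y)), b["K_N"][0]), b["K_N"][1])
        drive = max(up["tauo"][0] + up["taup"][0], 1e-6) \
            * max(1.0 - y[0] / Kg, 0.05)
        lam = min(s0 / drive, b["lambda_N_tauo"][1])
        lamp = min(s0 / drive, b["lambda_N_taup"][1])
        return [max(lam, 1e-8), max(lamp, 1e-8), Kg, max(y[0], 1e-6)]
    # C stage
    Kg = min(max(1.2 * float(np.max(y)), b["K_C"][0]), b["K_C"][1])
    lct = base.get("lambda_Ctau", 0.0)
    drive = max(up["N"][0], 1e-6)
    num = s0 / max(1.0 - y[0] / Kg, 0.05) - lct * up["taup"][0]
    lam = min(max(num / drive, 1e-4), b["lambda_CN"][1])
    return [lam, Kg, max(y[0], 1e-6)]


def sequential_fit(record: LongitudinalRecord,
                   bounds: Mapping[str, tuple[float, float]] | None = None,
                   step: float = 0.01, T0: float = _DEFAULT_T0,
                   lambda_Ctau_init: float = 0.0
                   ) -> tuple[SubjectParameters, dict[str, StageFit]]:
    """Equation-by-equation warm start over all five biomarkers.

    Stages run in cascade order; each requires at least three datapoints
    of its biomarker.  ``lambda_Ctau_init`` seeds the tau->cognition
    coupling, which only the joint refinement adjusts.
    """
    b = bounds or default_bounds(record)
    stages: dict[str, StageFit] = {}
    stages["Abeta"] = fit_abeta(record, b, T0)
    fixed = dict(stages["Abeta"].values)
    for stage in ("taup", "tauo", "N"):
        stages[stage] = fit_stage(stage, record, fixed, b, step, T0)
        fixed.update(stages[stage].values)
    fixed["lambda_Ctau"] = lambda_Ctau_init
    stages["C"] = fit_stage("C", record, fixed, b, step, T0)
    fixed.update(stages["C"].values)
    fixed["T0"] = T0
    params = SubjectParameters.from_dict({**{"lambda_Ctau": lambda_Ctau_init},
                                          **fixed})
    return params, stages


# ---------------------------------------------------------------------------
# Joint refinement and the top-level calibrate()
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Fitted parameters with residual diagnostics for one subject."""

    subject_id: str
    params: SubjectParameters
    stagewise_sse: dict[str, float]
    joint_objective: float
    relative_errors: dict[str, float]
    flags: list[str] = field(default_factory=list)


def fit_joint(record: LongitudinalRecord, init: SubjectParameters,
              bounds: Mapping[str, tuple[float, float]] | None = None,
              step: float = 0.01,
              weights: Mapping[str, float] | None = None,
              max_nfev: int | None = None
              ) -> tuple[SubjectParameters, float, list[str]]:
    """Joint local refinement of all 16 parameters from ``init``.

    Guaranteed never to return a point worse than ``init``: if the local
    solver fails or ends higher (within solver tolerance), the warm start
    is returned with a warning flag instead.
    """
    b = bounds or default_bounds(record)
    targets = {bm: record.ages(bm) for bm in STATE_NAMES if record.has(bm)}
    for bm in targets:
        record.require(bm)
    obs = {bm: record.values(bm) for bm in targets}
    w = {bm: math.sqrt(1.0 if weights is None else weights.get(bm, 1.0))
         for bm in targets}
    order = list(targets)

    def resid(x):
        pred = _predict(x, init.T0, targets, step)
        return np.concatenate([w[bm] * (pred[bm] - obs[bm]) for bm in order])

    lo = np.array([b[n][0] for n in RATE_PARAM_NAMES]
                  + [b[n][0] for n in IC_NAMES])
    hi = np.array([b[n][1] for n in RATE_PARAM_NAMES]
                  + [b[n][1] for n in IC_NAMES])
    x0 = np.clip(_pack(init), lo, hi)
    r0 = resid(x0)
    j0 = float(r0 @ r0)
    flags: list[str] = []
    try:
        res = _ls(resid, x0, lo, hi, max_nfev=max_nfev)
    except Exception as exc:  # solver blow-up: keep the warm start
        flags.append(f"joint_solver_failed: {exc}")
        return _unpack(x0, init.T0), j0, flags
    j1 = 2.0 * float(res.cost)
    if j1 > j0 + 1e-12 + 1e-9 * j0:
        flags.append("joint_no_improvement")
        return _unpack(x0, init.T0), j0, flags
    return _unpack(res.x, init.T0), j1, flags


def calibrate(record: LongitudinalRecord, joint: bool = True,
              bounds: Mapping[str, tuple[float, float]] | None = None,
              step: float = 0.01, T0: float = _DEFAULT_T0,
              relative_error_form: str = "mad",
              weights: Mapping[str, float] | None = None,
              max_nfev: int | None = None) -> CalibrationResult:
    """Full calibration of one subject: sequential warm start, optional
    joint refinement, and per-biomarker relative errors on the training
    data."""
    b = bounds or default_bounds(record)
    params, stages = sequential_fit(record, b, step, T0)
    flags = [f"{s.stage}: {s.message}" for s in stages.values()
             if not s.identifiable]
    if joint:
        params, j, jflags = fit_joint(record, params, b, step, weights,
                                      max_nfev)
        flags.extend(jflags)
    else:
        j = joint_sse(params, record, step, weights)
    targets = {bm: record.ages(bm) for bm in STATE_NAMES if record.has(bm)}
    pred = _predict(_pack(params), T0, targets, step)
    rel = {}
    for bm in targets:
        obs = record.values(bm)
        if np.any(obs == 0):
            flags.append(f"{bm}: zero observation, relative error undefined")
            rel[bm] = float("nan")
        else:
            rel[bm] = relative_error(pred[bm], obs, relative_error_form)
    return CalibrationResult(record.subject_id, params,
                             {s: f.sse for s, f in stages.items()},
                             j, rel, flags)


def fit_joint_random_restarts(record: LongitudinalRecord, k: int, seed: int,
                              bounds=None, step: float = 0.01,
                              T0: float = _DEFAULT_T0,
                              max_nfev: int = 200) -> float:
    """Best joint objective over ``k`` random starts drawn uniformly from
    the parameter box -- the baseline the sequential warm start is meant
    to beat."""
    b = bounds or default_bounds(record)
    rng = np.random.default_rng(seed)
    lo = np.array([b[n][0] for n in RATE_PARAM_NAMES]
                  + [b[n][0] for n in IC_NAMES])
    hi = np.array([b[n][1] for n in RATE_PARAM_NAMES]
                  + [b[n][1] for n in IC_NAMES])
    best = math.inf
    for _ in range(k):
        x = lo + rng.random(lo.size) * (hi - lo)
        start = _unpack(x, T0)
        try:
            _, j, _ = fit_joint(record, start, b, step, max_nfev=max_nfev)
        except IntegrationError:
            continue
        best = min(best, j)
    return best


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

def results_frame(results: Sequence[CalibrationResult]) -> pd.DataFrame:
    """One row per subject: parameters, joint objective, relative errors."""
    rows = []
    for r in results:
        row: dict = {"subject_id": r.subject_id}
        row.update(r.params.to_dict())
        row["joint_objective"] = r.joint_objective
        for bm, v in r.relative_errors.items():
            row[f"rel_err_{bm}"] = v
        row["flags"] = "; ".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(frame: pd.DataFrame,
                   group_col: str = "group") -> pd.DataFrame:
    """Mean +/- std of every numeric column per group label."""
    num = frame.select_dtypes("number").columns
    g = frame.groupby(group_col)[list(num)]
    mean, std = g.mean(), g.std(ddof=1)
    out = mean.copy()
    for c in num:
        out[c] = [f"{m:.4g} ± {s:.4g}" for m, s in zip(mean[c], std[c])]
    return out.reset_index()
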