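"""Five-state biomarker cascade model of Alzheimer's disease progression.

The model tracks five clinical biomarkers along the amyloid cascade:
amyloid-beta burden (``Abeta``), phosphorylated tau (``taup``),
non-amyloid (age/SNAP-related) tauopathy (``tauo``), neurodegeneration
(``N``, e.g. normalized hippocampal atrophy), and cognitive impairment
(``C``, e.g. ADAS13).  Amyloid follows logistic growth; it drives
phosphorylation of tau, which together with age-related tau drives
neurodegeneration; neurodegeneration and tau pathology drive cognitive
decline.  Anti-amyloid-beta therapy enters as a time-varying clearance
rate ``u(t)`` that removes amyloid proportionally to its level:

    dAb/dt  = lam_Ab * Ab * (1 - Ab/K_Ab) - u(t) * Ab
    dtp/dt  = lam_tau * Ab * (1 - tp/K_tp)
    dto/dt  = lam_tauo
    dN/dt   = (lam_Nto * to + lam_Ntp * tp) * (1 - N/K_N)
    dC/dt   = (lam_CN * N + lam_Ct * tp) * (1 - C/K_C)

All rates are per year and ages/times are in years.  The untreated
amyloid equation has the closed-form logistic solution used both for
calibration and as an integration oracle.

Integration uses a fixed-step classical 4th-order Runge-Kutta scheme on
a uniform grid so that forward state and backward adjoint solves (see
:mod:`adcascade.control`) share one grid.  Controls are stored as
grid-point values and linearly interpolated in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATE_NAMES",
    "RATE_PARAM_NAMES",
    "IC_NAMES",
    "IntegrationError",
    "SubjectParameters",
    "BiomarkerTrajectory",
    "cascade_rhs",
    "analytic_abeta",
    "simulate",
]

STATE_NAMES = ("Abeta", "taup", "tauo", "N", "C")

#: The 11 rate/capacity parameters, in the packing order used internally.
RATE_PARAM_NAMES = (
    "lambda_Abeta",
    "K_Abeta",
    "lambda_tau",
    "K_taup",
    "lambda_tauo",
    "lambda_N_tauo",
    "lambda_N_taup",
    "K_N",
    "lambda_CN",
    "lambda_Ctau",
    "K_C",
)

IC_NAMES = ("A0", "taup0", "tauo0", "N0", "C0")

#: Absolute round-off guard: a state this far below zero after an RK4 step
#: is clipped to zero; anything lower is an integration failure.
NEG_CLIP_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Fixed-step integration produced a non-finite or negative state."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class SubjectParameters:
    """Rates, carrying capacities and initial conditions for one subject.

    Initial conditions are the biomarker values at the reference age
    ``T0`` (50 years by default, just below the youngest observed age in
    the cohorts this model is built for), from which every trajectory is
    integrated forward.
    """

    lambda_Abeta: float
    K_Abeta: float
    lambda_tau: float
    K_taup: float
    lambda_tauo: float
    lambda_N_tauo: float
    lambda_N_taup: float
    K_N: float
    lambda_CN: float
    lambda_Ctau: float
    K_C: float
    A0: float
    taup0: float
    tauo0: float
    N0: float
    C0: float
    T0: float = 50.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
        for name in RATE_PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("K_Abeta", "K_taup", "K_N", "K_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for ic, cap in (("A0", "K_Abeta"), ("taup0", "K_taup"),
                        ("N0", "K_N"), ("C0", "K_C")):
            v = getattr(self, ic)
            if v < 0 or v > getattr(self, cap):
                raise ValueError(f"{ic}={v} outside [0, {cap}]")
        if self.tauo0 < 0:
            raise ValueError("tauo0 must be >= 0")
        if self.T0 < 0:
            raise ValueError("T0 must be >= 0")

    # -- packing helpers -------------------------------------------------
    def rate_array(self) -> np.ndarray:
        """The 11 rate/capacity parameters as a float64 array."""
        return np.array([getattr(self, n) for n in RATE_PARAM_NAMES], float)

    def initial_state(self) -> np.ndarray:
        return np.array([self.A0, self.taup0, self.tauo0, self.N0, self.C0],
                        float)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "SubjectParameters":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_config(self) -> str:
        """Flat ``key = value`` text block (one parameter per line)."""
        return "\n".join(f"{f.name} = {getattr(self, f.name)!r}"
                         for f in fields(self)) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SubjectParameters":
        d: dict[str, float] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            d[key.strip()] = float(val)
        return cls.from_dict(d)

    def with_(self, **updates: float) -> "SubjectParameters":
        return replace(self, **updates)


@dataclass
class BiomarkerTrajectory:
    """A simulated trajectory: uniform time grid plus the five state series."""

    times: np.ndarray          # strictly increasing ages, years
    states: np.ndarray         # shape (len(times), 5), columns STATE_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must have shape (len(times), 5)")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def series(self, biomarker: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(biomarker)]

    @property
    def Abeta(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 4]

    def value_at(self, t, biomarker: str) -> np.ndarray | float:
        """Linear interpolation of one biomarker series at age(s) ``t``."""
        return np.interp(t, self.times, self.series(biomarker))

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "age", self.times)
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df

    def write(self, path, subject_id: str = "subject") -> None:
        """Tidy delimited text: subject_id, age, Abeta, taup, tauo, N, C."""
        self.to_frame(subject_id).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Right-hand side and closed form
# ---------------------------------------------------------------------------

def cascade_rhs(state: Sequence[float], params: SubjectParameters,
                u: float = 0.0) -> np.ndarray:
    """Time derivative of the five-state cascade at ``state`` with clearance ``u``.

    ``u`` is the anti-amyloid clearance rate (per year); the untreated
    system is ``u = 0``.
    """
    y = np.asarray(state, float)
    if y.shape != (5,):
        raise ValueError("state must have 5 components")
    if np.any(y < 0):
        raise ValueError("state components must be >= 0")
    if u < 0:
        raise ValueError("clearance rate u must be >= 0")
    A, tp, to, n, c = y
    p = params
    return np.array([
        p.lambda_Abeta * A * (1.0 - A / p.K_Abeta) - u * A,
        p.lambda_tau * A * (1.0 - tp / p.K_taup),
        p.lambda_tauo,
        (p.lambda_N_tauo * to + p.lambda_N_taup * tp) * (1.0 - n / p.K_N),
        (p.lambda_CN * n + p.lambda_Ctau * tp) * (1.0 - c / p.K_C),
    ])


def analytic_abeta(t, params: SubjectParameters):
    """Closed-form untreated amyloid level at age(s) ``t``.

    The logistic equation dAb/dt = lam*Ab*(1 - Ab/K), Ab(T0) = A0 has the
    solution ``K / (C1 * exp(-lam*(t - T0)) + 1)`` with ``C1 = K/A0 - 1``.
    ``A0 = 0`` is the fixed point and yields identically zero.
    """
    t = np.asarray(t, float)
    if np.any(t < params.T0):
        raise ValueError("t must be >= T0")
    if params.A0 > params.K_Abeta:
        raise ValueError("A0 must be <= K_Abeta")
    if params.A0 == 0.0:
        out = np.zeros_like(t)
        return out if out.ndim else 0.0
    c1 = params.K_Abeta / params.A0 - 1.0
    out = params.K_Abeta / (c1 * np.exp(-params.lambda_Abeta * (t - params.T0)) + 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fixed-step RK4 kernels (numba-accelerated with a pure-Python fallback)
# ---------------------------------------------------------------------------

def _rk4_forward_py(y0, t0, h, n, p, u_nodes):
    """RK4 integration of the cascade on n uniform steps.

    ``u_nodes`` holds the clearance rate at the n+1 grid points; values at
    half-steps are the average of the adjacent nodes (linear interpolation).
    Returns (states, status, bad_index): status 0 ok, 1 non-finite,
    2 negative beyond the round-off guard.
    """
    lA, KA, lt, Ktp, lto, lNo, lNp, KN, lCN, lCt, KC = p
    out = np.empty((n + 1, 5))
    a, tp, to, nn, c = y0[0], y0[1], y0[2], y0[3], y0[4]
    out[0, 0] = a; out[0, 1] = tp; out[0, 2] = to; out[0, 3] = nn; out[0, 4] = c
    for k in range(n):
        u0 = u_nodes[k]
        u1 = u_nodes[k + 1]
        um = 0.5 * (u0 + u1)
        # k1
        d1a = lA * a * (1.0 - a / KA) - u0 * a
        d1b = lt * a * (1.0 - tp / Ktp)
        d1c = lto
        d1d = (lNo * to + lNp * tp) * (1.0 - nn / KN)
        d1e = (lCN * nn + lCt * tp) * (1.0 - c / KC)
        # k2 at midpoint
        a2 = a + 0.5 * h * d1a; tp2 = tp + 0.5 * h * d1b
        to2 = to + 0.5 * h * d1c; n2 = nn + 0.5 * h * d1d
        c2 = c + 0.5 * h * d1e
        d2a = lA * a2 * (1.0 - a2 / KA) - um * a2
        d2b = lt * a2 * (1.0 - tp2 / Ktp)
        d2c = lto
        d2d = (lNo * to2 + lNp * tp2) * (1.0 - n2 / KN)
        d2e = (lCN * n2 + lCt * tp2) * (1.0 - c2 / KC)
        # k3 at midpoint
        a3 = a + 0.5 * h * d2a; tp3 = tp + 0.5 * h * d2b
        to3 = to + 0.5 * h * d2c; n3 = nn + 0.5 * h * d2d
        c3 = c + 0.5 * h * d2e
        d3a = lA * a3 * (1.0 - a3 / KA) - um * a3
        d3b = lt * a3 * (1.0 - tp3 / Ktp)
        d3c = lto
        d3d = (lNo * to3 + lNp * tp3) * (1.0 - n3 / KN)
        d3e = (lCN * n3 + lCt * tp3) * (1.0 - c3 / KC)
        # k4 at endpoint
        a4 = a + h * d3a; tp4 = tp + h * d3b
        to4 = to + h * d3c; n4 = nn + h * d3d
        c4 = c + h * d3e
        d4a = lA * a4 * (1.0 - a4 / KA) - u1 * a4
        d4b = lt * a4 * (1.0 - tp4 / Ktp)
        d4c = lto
        d4d = (lNo * to4 + lNp * tp4) * (1.0 - n4 / KN)
        d4e = (lCN * n4 + lCt * tp4) * (1.0 - c4 / KC)
        s = h / 6.0
        a = a + s * (d1a + 2.0 * d2a + 2.0 * d3a + d4a)
        tp = tp + s * (d1b + 2.0 * d2b + 2.0 * d3b + d4b)
        to = to + s * (d1c + 2.0 * d2c + 2.0 * d3c + d4c)
        nn = nn + s * (d1d + 2.0 * d2d + 2.0 * d3d + d4d)
        c = c + s * (d1e + 2.0 * d2e + 2.0 * d3e + d4e)
        if not (math.isfinite(a) and math.isfinite(tp) and math.isfinite(to)
                and math.isfinite(nn) and math.isfinite(c)):
            return out, 1, k + 1
        if a < 0.0:
            if a > -NEG_CLIP_TOL:
                a = 0.0
            else:
                return out, 2, k + 1
        if tp < 0.0:
            if tp > -NEG_CLIP_TOL:
                tp = 0.0
            else:
                return out, 2, k + 1
        if to < 0.0:
            if to > -NEG_CLIP_TOL:
                to = 0.0
            else:
                return out, 2, k + 1
        if nn < 0.0:
            if nn > -NEG_CLIP_TOL:
                nn = 0.0
            else:
                return out, 2, k + 1
        if c < 0.0:
            if c > -NEG_CLIP_TOL:
                c = 0.0
            else:
                return out, 2, k + 1
        out[k + 1, 0] = a; out[k + 1, 1] = tp; out[k + 1, 2] = to
        out[k + 1, 3] = nn; out[k + 1, 4] = c
    return out, 0, -1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _rk4_forward = njit(cache=False)(_rk4_forward_py)
except Exception:  # pragma: no cover
    _rk4_forward = _rk4_forward_py


def _grid(t_start: float, t_end: float, step: float) -> tuple[int, float]:
    """Number of RK4 steps and the adjusted step landing exactly on t_end."""
    if t_end <= t_start:
        raise ValueError("t_end must be > t_start")
    if step <= 0:
        raise ValueError("step must be > 0")
    n = max(1, int(round((t_end - t_start) / step)))
    return n, (t_end - t_start) / n


def _raise_on_status(status: int, bad: int, t0: float, h: float) -> None:
    if status == 1:
        raise IntegrationError("non-finite state during integration",
                               time=t0 + bad * h)
    if status == 2:
        raise IntegrationError("state went negative beyond round-off guard",
                               time=t0 + bad * h)


def integrate_grid(y0: np.ndarray, t_start: float, t_end: float, step: float,
                   params: SubjectParameters,
                   u_nodes: np.ndarray | None = None) -> BiomarkerTrajectory:
    """Low-level fixed-grid RK4 solve with control given at grid nodes."""
    n, h = _grid(t_start, t_end, step)
    if u_nodes is None:
        u_nodes = np.zeros(n + 1)
    u_nodes = np.asarray(u_nodes, float)
    if u_nodes.shape != (n + 1,):
        raise ValueError(f"u_nodes must have {n + 1} entries")
    if np.any(u_nodes < 0):
        raise ValueError("control values must be >= 0")
    states, status, bad = _rk4_forward(np.asarray(y0, float), t_start, h, n,
                                       params.rate_array(), u_nodes)
    _raise_on_status(status, bad, t_start, h)
    times = t_start + h * np.arange(n + 1)
    times[-1] = t_end
    return BiomarkerTrajectory(times, states)


def simulate(params: SubjectParameters, t_start: float, t_end: float,
             control: Callable[[float], float] | None = None,
             step: float = 0.01) -> BiomarkerTrajectory:
    """Simulate the cascade from ``t_start`` to ``t_end`` on a uniform grid.

    If ``t_start`` is later than the subject's reference age ``T0``, the
    untreated system is first integrated from ``T0`` to ``t_start`` (the
    pre-treatment burn-in) so the starting state is model-consistent.
    ``control``, if given, is evaluated at the grid nodes and linearly
    interpolated in between; ``None`` means untreated.
    """
    if t_start < params.T0:
        raise ValueError("t_start must be >= T0")
    y0 = params.initial_state()
    if t_start > params.T0:
        burn = integrate_grid(y0, params.T0, t_start, step, params)
        y0 = burn.states[-1]
    n, h = _grid(t_start, t_end, step)
    if control is None:
        u_nodes = None
    else:
        times = t_start + h * np.arange(n + 1)
        u_nodes = np.array([float(control(t)) for t in times])
    return integrate_grid(y0, t_start, t_end, step, params, u_nodes)
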