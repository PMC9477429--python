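"""Personalized optimal anti-amyloid-beta therapy via Pontryagin's principle.

The treatment-planning problem on an interval [T1, T2] (ages in years)
seeks the clearance schedule u(t) in [0, u_max] minimizing

    J(u) = a1*Ab(T2) + a2*C(T2) + int_T1^T2 C dt + int_T1^T2 eps(Ab,t) u^2 dt

i.e. terminal amyloid and cognition, accumulated cognitive burden, and a
quadratic dosing penalty whose weight

    eps(Ab, t) = eps0 * Ab * exp(-gamma * (t - T1))

scales with amyloid burden (the ARIA side-effect risk of anti-amyloid
antibodies grows with plaque load) and decays over time on treatment
(side effects concentrate early, during dose ramp-up).

Pontryagin's Maximum Principle gives adjoint (costate) dynamics
dL_i/dt = -dH/dx_i with transversality conditions L1(T2) = a1,
L5(T2) = a2, others zero, and the interior optimality condition
dH/du = 2*eps*u - Ab*L1 = 0, clamped to the control box.  The coupled
two-point boundary value problem is solved by the forward-backward
sweep: forward RK4 state solve, backward RK4 adjoint solve on the same
grid, pointwise control update, relaxation, repeat until the states,
adjoints, and control all stop moving.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (BiomarkerTrajectory, SubjectParameters, _grid,
                    _raise_on_status, _rk4_forward, integrate_grid, simulate)

__all__ = [
    "OCConfig",
    "ControlSolution",
    "side_effect_weight",
    "objective",
    "adjoint_rhs",
    "control_update",
    "control_gradient",
    "forward_backward_sweep",
]

logger = logging.getLogger(__name__)

_EPS_FLOOR = 1e-300   # below this the quadratic penalty is treated as absent


@dataclass(frozen=True)
class OCConfig:
    """Weights, drug limits, horizon and solver settings for one control run."""

    u_max: float                 # maximum clearance rate, per year
    T1: float                    # treatment start age, years
    T2: float                    # treatment end age, years
    alpha1: float = 1.0          # terminal amyloid weight
    alpha2: float = 1.0          # terminal cognition weight
    eps0: float = 5.0            # side-effect scale
    gamma: float = 2.0           # side-effect decay rate, per year
    step: float = 0.01           # grid spacing, years
    relax: float = 0.5           # sweep relaxation weight in (0, 1]
    tol: float = 1e-4            # relative sup-norm convergence tolerance
    max_iter: int = 500
    adjoint_form: str = "derived"   # "derived" (full -dH/dC) or "printed"

    def __post_init__(self) -> None:
        if self.u_max < 0:
            raise ValueError("u_max must be >= 0")
        if self.T2 <= self.T1:
            raise ValueError("T2 must be > T1")
        if not 0.0 < self.relax <= 1.0:
            raise ValueError("relax must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.adjoint_form not in ("derived", "printed"):
            raise ValueError("adjoint_form must be 'derived' or 'printed'")


def side_effect_weight(Abeta, t_since_start, eps0: float = 5.0,
                       gamma: float = 2.0):
    """Side-effect weight eps = eps0 * Ab * exp(-gamma * t_since_start)."""
    Abeta = np.asarray(Abeta, float)
    if np.any(Abeta < 0):
        raise ValueError("Abeta must be >= 0")
    out = eps0 * Abeta * np.exp(-gamma * np.asarray(t_since_start, float))
    return out if out.ndim else float(out)


def objective(states: BiomarkerTrajectory, u: np.ndarray,
              cfg: OCConfig) -> float:
    """Objective J(u) evaluated by the composite trapezoid rule on the grid."""
    u = np.asarray(u, float)
    t = states.times
    if u.shape != t.shape:
        raise ValueError("control and trajectory grids do not match")
    eps = side_effect_weight(states.Abeta, t - t[0], cfg.eps0, cfg.gamma)
    return float(cfg.alpha1 * states.Abeta[-1] + cfg.alpha2 * states.C[-1]
                 + np.trapezoid(states.C, t)
                 + np.trapezoid(eps * u * u, t))


def control_update(Abeta, L1, eps, u_max: float):
    """Clamped optimality update u = min(u_max, max(0, L1*Ab / (2*eps))).

    When the side-effect weight vanishes (e.g. amyloid fully cleared) the
    penalty is absent and the update degenerates to bang-bang: u_max
    where the Hamiltonian decreases with u, else 0.
    """
    Abeta = np.asarray(Abeta, float)
    L1 = np.asarray(L1, float)
    eps = np.asarray(eps, float)
    drive = L1 * Abeta
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(eps > _EPS_FLOOR, drive / (2.0 * eps),
                       np.where(drive > 0.0, u_max, 0.0))
    out = np.clip(raw, 0.0, u_max)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Adjoint system
# ---------------------------------------------------------------------------

def _adjoint_deriv_py(L, S, u, tprime, p, eps0, gamma, full):
    """Forward-time derivative dL/dt = -dH/dx of the adjoint vector."""
    lA, KA, lt, Ktp, lto, lNo, lNp, KN, lCN, lCt, KC = p
    A, tp, to, nn, c = S[0], S[1], S[2], S[3], S[4]
    L1, L2, L3, L4, L5 = L[0], L[1], L[2], L[3], L[4]
    eps_t = eps0 * math.exp(-gamma * tprime)
    d1 = (-eps_t * u * u
          + (2.0 * lA * A / KA - lA + u) * L1
          - lt * (1.0 - tp / Ktp) * L2)
    d2 = (lt * A / Ktp * L2
          - lNp * (1.0 - nn / KN) * L4
          - lCt * (1.0 - c / KC) * L5)
    d3 = -lNo * (1.0 - nn / KN) * L4
    d4 = ((lNo * to + lNp * tp) / KN * L4
          - lCN * (1.0 - c / KC) * L5)
    ct = lCt * tp if full else 0.0
    d5 = -1.0 + (lCN * nn + ct) / KC * L5
    return np.array([d1, d2, d3, d4, d5])


def _rk4_adjoint_py(states, u_nodes, h, n, p, eps0, gamma, a1, a2, full):
    """Backward RK4 solve of the adjoint system on the shared grid.

    States and control at half-steps are linear interpolants (averages of
    the adjacent nodes).  Time origin for the side-effect decay is the
    first grid node (treatment start).
    """
    L = np.empty((n + 1, 5))
    L[n, 0] = a1; L[n, 1] = 0.0; L[n, 2] = 0.0; L[n, 3] = 0.0; L[n, 4] = a2
    Sh = np.empty(5)
    y2 = np.empty(5)
    for k in range(n - 1, -1, -1):
        tp_hi = (k + 1) * h
        tp_mid = (k + 0.5) * h
        tp_lo = k * h
        for j in range(5):
            Sh[j] = 0.5 * (states[k, j] + states[k + 1, j])
        uh = 0.5 * (u_nodes[k] + u_nodes[k + 1])
        k1 = _adjoint_deriv(L[k + 1], states[k + 1], u_nodes[k + 1], tp_hi,
                            p, eps0, gamma, full)
        for j in range(5):
            y2[j] = L[k + 1, j] - 0.5 * h * k1[j]
        k2 = _adjoint_deriv(y2, Sh, uh, tp_mid, p, eps0, gamma, full)
        for j in range(5):
            y2[j] = L[k + 1, j] - 0.5 * h * k2[j]
        k3 = _adjoint_deriv(y2, Sh, uh, tp_mid, p, eps0, gamma, full)
        for j in range(5):
            y2[j] = L[k + 1, j] - h * k3[j]
        k4 = _adjoint_deriv(y2, states[k], u_nodes[k], tp_lo,
                            p, eps0, gamma, full)
        for j in range(5):
            L[k, j] = L[k + 1, j] - h / 6.0 * (k1[j] + 2.0 * k2[j]
                                               + 2.0 * k3[j] + k4[j])
    return L


try:  # pragma: no cover
    from numba import njit

    _adjoint_deriv = njit(cache=False)(_adjoint_deriv_py)
    # the compiled backward solver resolves _adjoint_deriv to the njit version
    _rk4_adjoint = njit(cache=False)(_rk4_adjoint_py)
except Exception:  # pragma: no cover
    _adjoint_deriv = _adjoint_deriv_py
    _rk4_adjoint = _rk4_adjoint_py


def adjoint_rhs(state, adj, u: float, t_since_start: float,
                params: SubjectParameters, cfg: OCConfig) -> np.ndarray:
    """Forward-time adjoint derivative dL/dt = -dH/dx at one point.

    With all adjoints zero and no dosing only the running cognitive cost
    survives: the derivative is (0, 0, 0, 0, -1).
    """
    state = np.asarray(state, float)
    adj = np.asarray(adj, float)
    if state.shape != (5,) or adj.shape != (5,):
        raise ValueError("state and adj must each have 5 components")
    if np.any(state < 0) or u < 0:
        raise ValueError("state components and u must be >= 0")
    return np.asarray(_adjoint_deriv_py(adj, state, float(u),
                                        float(t_since_start),
                                        params.rate_array(), cfg.eps0,
                                        cfg.gamma,
                                        cfg.adjoint_form == "derived"))


def solve_adjoint(states: BiomarkerTrajectory, u: np.ndarray,
                  params: SubjectParameters, cfg: OCConfig) -> np.ndarray:
    """Backward adjoint solve over a forward trajectory; returns (n+1, 5)."""
    t = states.times
    h = t[1] - t[0]
    n = t.size - 1
    return np.asarray(_rk4_adjoint(states.states, np.asarray(u, float), h, n,
                                   params.rate_array(), cfg.eps0, cfg.gamma,
                                   cfg.alpha1, cfg.alpha2,
                                   cfg.adjoint_form == "derived"))


def control_gradient(states: BiomarkerTrajectory, adjoints: np.ndarray,
                     u: np.ndarray, cfg: OCConfig) -> np.ndarray:
    """Pointwise Hamiltonian gradient dH/du = 2*eps*u - Ab*L1 on the grid."""
    t = states.times
    eps = side_effect_weight(states.Abeta, t - t[0], cfg.eps0, cfg.gamma)
    return 2.0 * eps * np.asarray(u, float) - states.Abeta * adjoints[:, 0]


# ---------------------------------------------------------------------------
# Forward-backward sweep
# ---------------------------------------------------------------------------

@dataclass
class ControlSolution:
    """Discretized optimal control with its state/adjoint trajectories."""

    times: np.ndarray
    u: np.ndarray
    states: BiomarkerTrajectory
    adjoints: np.ndarray
    objective: float
    iterations: int
    converged: bool
    history: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        df = self.states.to_frame()
        df.insert(1, "u", self.u)
        for i in range(5):
            df[f"L{i + 1}"] = self.adjoints[:, i]
        return df

    def summary(self) -> dict:
        return {"objective": self.objective, "iterations": self.iterations,
                "converged": self.converged}


def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    return float(np.max(np.abs(new - old))
                 / (np.max(np.abs(old)) + 1e-12))


def forward_backward_sweep(params: SubjectParameters,
                           cfg: OCConfig) -> ControlSolution:
    """Solve the optimality system by forward-backward sweep iteration.

    The control starts at zero; each iteration solves the states forward,
    the adjoints backward, applies the clamped optimality update, and
    relaxes ``u <- relax*u_new + (1-relax)*u_old``.  Convergence is the
    maximum over the state/adjoint/control blocks of the relative
    sup-norm change between iterations.  If the objective rises for five
    consecutive iterations the relaxation weight is halved.
    """
    if cfg.T1 < params.T0:
        raise ValueError("treatment start T1 must be >= T0")
    y0 = params.initial_state()
    if cfg.T1 > params.T0:
        y0 = simulate(params, params.T0, cfg.T1, step=cfg.step).states[-1]

    n, h = _grid(cfg.T1, cfg.T2, cfg.step)
    times = cfg.T1 + h * np.arange(n + 1)
    times[-1] = cfg.T2
    p = params.rate_array()
    full = cfg.adjoint_form == "derived"
    relax = cfg.relax

    u = np.zeros(n + 1)
    prev_states = None
    prev_adj = None
    history: list[float] = []
    converged = False
    states = None
    adj = None
    it = 0

    for it in range(1, cfg.max_iter + 1):
        raw, status, bad = _rk4_forward(y0, cfg.T1, h, n, p, u)
        _raise_on_status(status, bad, cfg.T1, h)
        states = BiomarkerTrajectory(times.copy(), raw)
        adj = np.asarray(_rk4_adjoint(raw, u, h, n, p, cfg.eps0, cfg.gamma,
                                      cfg.alpha1, cfg.alpha2, full))
        eps = side_effect_weight(states.Abeta, times - cfg.T1,
                                 cfg.eps0, cfg.gamma)
        u_new = control_update(states.Abeta, adj[:, 0], eps, cfg.u_max)
        u_next = relax * u_new + (1.0 - relax) * u
        history.append(objective(states, u, cfg))

        if prev_states is not None:
            metric = max(_rel_change(states.states, prev_states),
                         _rel_change(adj, prev_adj),
                         _rel_change(u_next, u))
            if metric <= cfg.tol:
                u = u_next
                converged = True
                break
        if len(history) >= 6 and all(history[-i] > history[-i - 1]
                                     for i in range(1, 6)):
            relax *= 0.5
            logger.warning("objective rose for 5 consecutive sweeps; "
                           "halving relaxation to %.3g", relax)
        prev_states = states.states
        prev_adj = adj
        u = u_next

    # final self-consistent solve with the converged control
    raw, status, bad = _rk4_forward(y0, cfg.T1, h, n, p, u)
    _raise_on_status(status, bad, cfg.T1, h)
    states = BiomarkerTrajectory(times.copy(), raw)
    adj = np.asarray(_rk4_adjoint(raw, u, h, n, p, cfg.eps0, cfg.gamma,
                                  cfg.alpha1, cfg.alpha2, full))
    J = objective(states, u, cfg)
    if not converged:
        logger.warning("forward-backward sweep did not converge in %d "
                       "iterations", cfg.max_iter)
    return ControlSolution(times=times, u=u, states=states, adjoints=adj,
                           objective=J, iterations=it, converged=converged,
                           history=history)
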