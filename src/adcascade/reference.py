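"""Published per-group parameter statistics for the cascade model.

Mean and standard deviation of every fitted rate, capacity and initial
condition for the three diagnostic groups of the calibration study
(AD: clinically probable Alzheimer's disease, LMCI: late mild cognitive
impairment, CN: cognitively normal), together with the group sizes.
These are the defaults of the synthetic-cohort generator and the source
of the default calibration bounds.

Units: rates per year; Abeta/taup/tauo in CSF-like biomarker units;
N normalized to ~1; C on the ADAS13 scale.  Initial conditions refer to
the reference age T0 = 50 years.
"""

from __future__ import annotations

from .model import IC_NAMES, RATE_PARAM_NAMES

__all__ = ["GROUP_STATS", "GROUP_SIZES", "PARAM_ORDER", "rate_upper_bounds"]

PARAM_ORDER = tuple(RATE_PARAM_NAMES) + tuple(IC_NAMES)

GROUP_SIZES = {"AD": 10, "LMCI": 32, "CN": 7}

# {group: {parameter: (mean, std)}}
GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "AD": {
        "A0": (36.03, 26.52),
        "taup0": (12.38, 14.47),
        "tauo0": (66.70, 58.57),
        "N0": (0.26, 0.08),
        "C0": (3.68, 8.30),
        "lambda_Abeta": (18.35e-2, 3.11e-2),
        "K_Abeta": (259.44, 13.21),
        "lambda_tau": (0.15, 0.16),
        "K_taup": (123.35, 81.63),
        "lambda_tauo": (1.15, 1.70),
        "lambda_N_tauo": (3.75e-4, 1.22e-4),
        "lambda_N_taup": (6.90e-3, 1.49e-3),
        "K_N": (1.00, 0.01),
        "lambda_CN": (1.67, 2.40),
        "lambda_Ctau": (3.83, 8.00),
        "K_C": (169.48, 63.35),
    },
    "LMCI": {
        "A0": (41.57, 24.23),
        "taup0": (4.21, 7.68),
        "tauo0": (28.66, 33.13),
        "N0": (0.48, 0.26),
        "C0": (6.03, 6.56),
        "lambda_Abeta": (16.12e-2, 5.03e-2),
        "K_Abeta": (264.99, 74.69),
        "lambda_tau": (0.08, 0.12),
        "K_taup": (131.66, 75.89),
        "lambda_tauo": (1.74, 2.08),
        "lambda_N_tauo": (4.24e-4, 1.03e-4),
        "lambda_N_taup": (7.37e-3, 1.07e-3),
        "K_N": (1.02, 0.05),
        "lambda_CN": (1.26, 1.99),
        "lambda_Ctau": (1.93, 3.91),
        "K_C": (129.40, 84.31),
    },
    "CN": {
        "A0": (44.92, 24.54),
        "taup0": (3.69, 6.15),
        "tauo0": (24.25, 26.98),
        "N0": (0.42, 0.10),
        "C0": (2.58, 2.60),
        "lambda_Abeta": (16.82e-2, 5.52e-2),
        "K_Abeta": (276.21, 88.29),
        "lambda_tau": (0.12, 0.17),
        "K_taup": (126.53, 91.31),
        "lambda_tauo": (0.87, 0.66),
        "lambda_N_tauo": (4.41e-4, 0.89e-4),
        "lambda_N_taup": (7.24e-3, 1.73e-3),
        "K_N": (1.03, 0.07),
        "lambda_CN": (3.16, 3.06),
        "lambda_Ctau": (2.48, 3.94),
        "K_C": (59.89, 80.03),
    },
}

_RATE_NAMES = ("lambda_Abeta", "lambda_tau", "lambda_tauo", "lambda_N_tauo",
               "lambda_N_taup", "lambda_CN", "lambda_Ctau")


def rate_upper_bounds(factor: float = 10.0) -> dict[str, float]:
    """Default upper bound for each rate: ``factor`` times the largest
    group mean (the calibration study states no bounds; this box keeps
    the ODE system well-posed without constraining realistic fits)."""
    return {name: factor * max(GROUP_STATS[g][name][0] for g in GROUP_STATS)
            for name in _RATE_NAMES}
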