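"""Anti-amyloid drug registry and clearance-rate calibration.

A published trial outcome of the form "amyloid burden fell by X% over W
weeks" is converted into a maximum clearance rate by assuming pure
exponential clearance at full dosing, dAb/dt = -u_max * Ab, so that

    fraction_remaining = exp(-u_max * W)   =>   u_max = -ln(f) / W.

Rates are stored per week (the unit trials report in) and converted to
per year (the model's internal unit) with a factor of 52 at the
optimal-control boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WEEKS_PER_YEAR",
    "DrugDefinition",
    "clearance_rate_from_reduction",
    "reduction_from_rate",
    "builtin_drugs",
    "get_drug",
    "parse_drug_spec",
]

WEEKS_PER_YEAR = 52.0


def clearance_rate_from_reduction(fraction_remaining: float,
                                  duration_weeks: float) -> float:
    """Clearance rate per week from the fraction of amyloid remaining.

    ``fraction_remaining`` is the end-of-trial amyloid level divided by
    baseline, in (0, 1]; ``duration_weeks`` is the trial length.
    """
    if not 0.0 < fraction_remaining <= 1.0:
        raise ValueError("fraction_remaining must be in (0, 1]")
    if duration_weeks <= 0:
        raise ValueError("duration_weeks must be > 0")
    return -math.log(fraction_remaining) / duration_weeks


def reduction_from_rate(rate_per_week: float, duration_weeks: float) -> float:
    """Percent amyloid reduction after ``duration_weeks`` of clearance."""
    if rate_per_week < 0:
        raise ValueError("rate must be >= 0")
    return 100.0 * (1.0 - math.exp(-rate_per_week * duration_weeks))


@dataclass(frozen=True)
class DrugDefinition:
    """One anti-amyloid agent, defined by its source trial observation.

    The clearance rate is derived from the observation at load time
    rather than storing a rounded constant, so downstream numbers stay
    self-consistent.
    """

    name: str
    source_fraction_remaining: float
    source_duration_weeks: float

    def __post_init__(self) -> None:
        if not 0.0 < self.source_fraction_remaining <= 1.0:
            raise ValueError("source_fraction_remaining must be in (0, 1]")
        if self.source_duration_weeks <= 0:
            raise ValueError("source_duration_weeks must be > 0")

    @property
    def u_max_per_week(self) -> float:
        return clearance_rate_from_reduction(self.source_fraction_remaining,
                                             self.source_duration_weeks)

    @property
    def u_max_per_year(self) -> float:
        return WEEKS_PER_YEAR * self.u_max_per_week

    def to_config_line(self) -> str:
        return (f"{self.name}:{self.source_fraction_remaining!r}"
                f":{self.source_duration_weeks!r}")


# Source observations:
#  - aducanumab low dose: amyloid PET down 16.5% at week 78,
#  - aducanumab high dose: down 27.2% at week 78,
#  - donanemab: florbetapir SUVr reduced by 84.13 from a baseline of
#    107.6 over 76 weeks, i.e. 23.47/107.6 remaining.
_DONANEMAB_BASELINE_SUVR = 107.6
_DONANEMAB_REDUCTION_SUVR = 84.13


def builtin_drugs() -> list[DrugDefinition]:
    """The three built-in agents with trial-derived clearance rates."""
    return [
        DrugDefinition("aducanumab-low", 1.0 - 0.165, 78.0),
        DrugDefinition("aducanumab-high", 1.0 - 0.272, 78.0),
        DrugDefinition(
            "donanemab",
            (_DONANEMAB_BASELINE_SUVR - _DONANEMAB_REDUCTION_SUVR)
            / _DONANEMAB_BASELINE_SUVR,
            76.0,
        ),
    ]


def get_drug(name: str) -> DrugDefinition:
    for d in builtin_drugs():
        if d.name == name:
            return d
    raise KeyError(f"unknown drug {name!r}; "
                   f"known: {[d.name for d in builtin_drugs()]}")


def parse_drug_spec(spec: str) -> DrugDefinition:
    """Parse a drug name or a ``custom:<fraction>:<weeks>`` spec."""
    if spec.startswith("custom:"):
        _, frac, weeks = spec.split(":")
        return DrugDefinition("custom", float(frac), float(weeks))
    return get_drug(spec)


def write_registry(drugs: list[DrugDefinition], path) -> None:
    with open(path, "w") as fh:
        fh.write("# name:fraction_remaining:duration_weeks\n")
        for d in drugs:
            fh.write(d.to_config_line() + "\n")


def read_registry(path) -> list[DrugDefinition]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, frac, weeks = line.split(":")
            out.append(DrugDefinition(name, float(frac), float(weeks)))
    return out
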