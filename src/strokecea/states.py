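"""Health-state spaces for the short-run (admission to 90 days) and long-run
(90 days to 10 years) cohort models.

Short-run states are hospital wards plus discharge locations; the ward mix
differs between the two service models: the centralized ("after") pathway
admits through hyper-acute stroke units (HASU) feeding stroke units (SU),
while the previous ("before") pathway used acute stroke units (ASU) and
stroke-rehabilitation wards. DEAD is absorbing in both models.
"""

from __future__ import annotations

from enum import Enum


class StateKind(str, Enum):
    INPATIENT = "inpatient"
    DISCHARGED = "discharged"
    ABSORBING = "absorbing"


class HealthState(str, Enum):
    """Short-run model states (ward type or discharge location)."""

    HASU = "HASU"
    ASU = "ASU"
    SU = "SU"
    STROKE_REHAB = "STROKE_REHAB"
    MEDICAL = "MEDICAL"
    SURGICAL = "SURGICAL"
    ICU = "ICU"
    HOME = "HOME"
    HOME_ESD = "HOME_ESD"
    NURSING_HOME = "NURSING_HOME"
    DEAD = "DEAD"


STATE_KIND: dict[str, StateKind] = {
    "HASU": StateKind.INPATIENT,
    "ASU": StateKind.INPATIENT,
    "SU": StateKind.INPATIENT,
    "STROKE_REHAB": StateKind.INPATIENT,
    "MEDICAL": StateKind.INPATIENT,
    "SURGICAL": StateKind.INPATIENT,
    "ICU": StateKind.INPATIENT,
    "HOME": StateKind.DISCHARGED,
    "HOME_ESD": StateKind.DISCHARGED,
    "NURSING_HOME": StateKind.DISCHARGED,
    "DEAD": StateKind.ABSORBING,
}

INPATIENT_STATES = tuple(s for s, k in STATE_KIND.items() if k is StateKind.INPATIENT)
DISCHARGED_STATES = tuple(s for s, k in STATE_KIND.items() if k is StateKind.DISCHARGED)

#: Ward states only valid in one period: HASUs exist only in the centralized
#: model; ASU and stroke-rehabilitation wards only in the previous model.
PERIOD_ONLY_WARDS = {"after": ("HASU",), "before": ("ASU", "STROKE_REHAB")}

PERIODS = ("before", "after")


def states_for_period(period: str) -> list[str]:
    """Ordered short-run state list for one period (DEAD last)."""
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    banned = set(PERIOD_ONLY_WARDS["after" if period == "before" else "before"])
    return [s.value for s in HealthState if s.value not in banned]


def validate_ward_for_period(ward: str, period: str) -> None:
    if ward in PERIOD_ONLY_WARDS["after"] and period == "before":
        raise ValueError(f"ward {ward} is only valid in the 'after' period")
    if ward in PERIOD_ONLY_WARDS["before"] and period == "after":
        raise ValueError(f"ward {ward} is only valid in the 'before' period")


class LongRunState(str, Enum):
    """Long-run model states: residence/disability bands plus DEAD.

    The home states partition the Barthel index: independent 15-20,
    moderate 10-14, dependent 0-9 (band cut-points are configurable
    defaults).
    """

    HOME_INDEPENDENT = "HOME_INDEPENDENT"
    HOME_MODERATE = "HOME_MODERATE"
    HOME_DEPENDENT = "HOME_DEPENDENT"
    INSTITUTIONAL_CARE = "INSTITUTIONAL_CARE"
    DEAD = "DEAD"


LONG_RUN_STATES = [s.value for s in LongRunState]

#: Barthel bands (inclusive low, inclusive high) for the three home states.
BARTHEL_BANDS = {
    "HOME_INDEPENDENT": (15, 20),
    "HOME_MODERATE": (10, 14),
    "HOME_DEPENDENT": (0, 9),
}


def barthel_band(score: int) -> str:
    """Map a Barthel score (0-20) to its home disability band."""
    if not 0 <= score <= 20:
        raise ValueError(f"Barthel score {score} outside [0, 20]")
    for name, (lo, hi) in BARTHEL_BANDS.items():
        if lo <= score <= hi:
            return name
    raise AssertionError("Barthel bands do not partition [0, 20]")
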