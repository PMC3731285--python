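"""90-days-to-10-years Markov model over residence/disability states.

Five states: three home states banded by Barthel index (independent 15-20,
moderate 10-14, dependent 0-9), institutional care, and DEAD. Cycles are 90
days; 40 cycles span the 10-year horizon. Survivors of the short-run model
are allocated at day 90: home discharges split across the home bands by a
Barthel mixture, nursing-home discharges enter institutional care, and
patients still in hospital follow a configurable rule (institutional care
by default; 'home' as a scenario).

The default transition matrices are a calibrated stand-in (assumption, not
published values): per-90-day mortality increases with dependence, with a
mild drift toward more dependent states. They ship as editable config.

Costs and QALYs over this horizon are discounted at an annual rate of 3.5%
using mid-cycle timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov_short import CohortTrace
from .states import LONG_RUN_STATES

__all__ = [
    "DiscountSpec",
    "LongRunTransitions",
    "default_long_run_transitions",
    "default_barthel_mixture",
    "seed_from_short_run",
    "discount_factor",
    "run_long_cohort",
]

N_LONG_CYCLES = 40
CYCLE_DAYS = 90.0


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied from the model start (day 0)."""

    annual_rate: float = 0.035

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("annual_rate must be >= 0")


def discount_factor(spec: DiscountSpec, day: float) -> float:
    """Discount factor (1 + rate)^(-day/365.25); 1.0 at day 0."""
    if day < 0:
        raise ValueError("day must be >= 0")
    return float((1.0 + spec.annual_rate) ** (-day / 365.25))


@dataclass(frozen=True)
class LongRunTransitions:
    """One row-stochastic matrix per 90-day cycle over LONG_RUN_STATES."""

    matrices: np.ndarray  # (n_cycles, 5, 5)
    source: str = "assumption: calibrated stand-in"

    def validate(self, atol: float = 1e-9) -> None:
        m = self.matrices
        n = len(LONG_RUN_STATES)
        if m.shape[1:] != (n, n):
            raise ValueError(f"matrices must be (cycles, {n}, {n})")
        if np.any(m < -atol):
            raise ValueError("negative transition probability")
        if not np.allclose(m.sum(axis=2), 1.0, atol=atol):
            raise ValueError("rows do not sum to 1")
        dead = LONG_RUN_STATES.index("DEAD")
        unit = np.zeros(n)
        unit[dead] = 1.0
        if not np.allclose(m[:, dead, :], unit, atol=atol):
            raise ValueError("DEAD row is not the unit vector")


#: Per-90-day transition probabilities used as the default stand-in.
#: Rows: from-state; keys: to-state. Remaining mass stays put.
DEFAULT_LONG_RUN_MOVES: dict[str, dict[str, float]] = {
    "HOME_INDEPENDENT": {"HOME_MODERATE": 0.020, "INSTITUTIONAL_CARE": 0.002, "DEAD": 0.015},
    "HOME_MODERATE": {"HOME_INDEPENDENT": 0.015, "HOME_DEPENDENT": 0.020,
                      "INSTITUTIONAL_CARE": 0.010, "DEAD": 0.025},
    "HOME_DEPENDENT": {"HOME_MODERATE": 0.010, "INSTITUTIONAL_CARE": 0.030, "DEAD": 0.050},
    "INSTITUTIONAL_CARE": {"DEAD": 0.080},
}


def default_long_run_transitions(n_cycles: int = N_LONG_CYCLES,
                                 moves: dict[str, dict[str, float]] | None = None
                                 ) -> LongRunTransitions:
    """Build cycle-constant default matrices from a per-state move table."""
    moves = DEFAULT_LONG_RUN_MOVES if moves is None else moves
    n = len(LONG_RUN_STATES)
    idx = {s: i for i, s in enumerate(LONG_RUN_STATES)}
    m = np.zeros((n, n))
    m[idx["DEAD"], idx["DEAD"]] = 1.0
    for src, row in moves.items():
        i = idx[src]
        total = 0.0
        for tgt, p in row.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{src}->{tgt}: probability {p} outside [0, 1]")
            m[i, idx[tgt]] = p
            total += p
        if total > 1.0 + 1e-12:
            raise ValueError(f"{src}: outgoing probabilities sum to {total} > 1")
        m[i, i] = 1.0 - total
    out = LongRunTransitions(matrices=np.repeat(m[None, :, :], n_cycles, axis=0))
    out.validate()
    return out


def default_barthel_mixture(mean: float, sd: float) -> dict[str, float]:
    """Home-band mixture implied by a normal 90-day Barthel distribution.

    Stand-in for register-derived 90-day Barthel bands: mass of
    N(mean, sd) clipped to [0, 20] falling in each band.
    """
    from scipy.stats import norm

    lo, hi = norm.cdf((0 - mean) / sd), norm.cdf((20 - mean) / sd)

    def band_mass(a: float, b: float) -> float:
        # clipping piles tail mass onto the extreme scores
        lo_b = norm.cdf((a - 0.5 - mean) / sd) if a > 0 else 0.0
        hi_b = norm.cdf((b + 0.5 - mean) / sd) if b < 20 else 1.0
        return hi_b - lo_b

    mix = {
        "HOME_INDEPENDENT": band_mass(15, 20),
        "HOME_MODERATE": band_mass(10, 14),
        "HOME_DEPENDENT": band_mass(0, 9),
    }
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def seed_from_short_run(trace: CohortTrace, barthel_mixture: dict[str, float],
                        inpatient_rule: str = "institutional") -> np.ndarray:
    """Allocate day-90 survivors to long-run states (counts over LONG_RUN_STATES).

    Home and ESD discharges split across home bands by ``barthel_mixture``;
    nursing-home discharges enter institutional care; patients still in
    hospital go to institutional care (default) or home per the scenario
    rule.
    """
    if abs(sum(barthel_mixture.values()) - 1.0) > 1e-9:
        raise ValueError("barthel_mixture does not sum to 1")
    if inpatient_rule not in ("institutional", "home"):
        raise ValueError(f"unknown inpatient_rule {inpatient_rule!r}")
    final = trace.occupancy[-1]
    idx = {s: i for i, s in enumerate(LONG_RUN_STATES)}
    out = np.zeros(len(LONG_RUN_STATES))

    home_mass = 0.0
    inpatient_mass = 0.0
    for i, s in enumerate(trace.states):
        if s == "DEAD":
            out[idx["DEAD"]] += final[i]
        elif s in ("HOME", "HOME_ESD"):
            home_mass += final[i]
        elif s == "NURSING_HOME":
            out[idx["INSTITUTIONAL_CARE"]] += final[i]
        else:  # still inpatient at day 90
            inpatient_mass += final[i]
    if inpatient_rule == "institutional":
        out[idx["INSTITUTIONAL_CARE"]] += inpatient_mass
    else:
        home_mass += inpatient_mass
    for band, p in barthel_mixture.items():
        out[idx[band]] += home_mass * p
    return out


def run_long_cohort(initial: np.ndarray, transitions: LongRunTransitions,
                    n_cycles: int = N_LONG_CYCLES) -> CohortTrace:
    """Propagate the long-run cohort; 90-day cycles, conservation asserted."""
    transitions.validate()
    if transitions.matrices.shape[0] < n_cycles:
        raise ValueError(f"need {n_cycles} matrices, got {transitions.matrices.shape[0]}")
    initial = np.asarray(initial, dtype=float)
    total = initial.sum()
    if total <= 0:
        raise ValueError("empty initial occupancy")
    occ = np.zeros((n_cycles + 1, len(LONG_RUN_STATES)))
    occ[0] = initial
    dead = LONG_RUN_STATES.index("DEAD")
    for c in range(n_cycles):
        occ[c + 1] = occ[c] @ transitions.matrices[c]
        if abs(occ[c + 1].sum() - total) > 1e-6 * max(total, 1.0):
            raise AssertionError(f"cohort not conserved at cycle {c + 1}")
        if occ[c + 1, dead] < occ[c, dead] - 1e-9 * total:
            raise AssertionError(f"DEAD occupancy decreased at cycle {c + 1}")
    return CohortTrace(states=tuple(LONG_RUN_STATES), occupancy=occ,
                       cohort_size=float(total), cycle_days=CYCLE_DAYS)
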