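"""Admission-to-90-days time-dependent Markov cohort model.

States are hospital wards plus discharge locations (see states.py); cycles
are one day. Each day's row-stochastic transition matrix is assembled from
fitted Weibull hazards: a period-wide death hazard applied to every alive
state (so the model's marginal survival reproduces the fitted survival
curve exactly), plus per-ward exit hazards whose exiting mass is split
across destination states by an empirical mixture.

Competing risks within a day are composed on the rate scale: each marginal
per-day probability p becomes a rate r = -ln(1-p); total exit probability
is 1 - exp(-sum r), allocated proportionally to rates. This is
order-independent and exact for constant-within-day hazards.

The 'before' arm carries two national-trend adjustments: a 30-day mortality
reduction (into-DEAD entries over days 0-29 scaled by one bisection-chosen
factor) and a stroke-unit length-of-stay reduction (exit-time Weibull scale
rescaled to drop the implied mean stay).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .states import STATE_KIND, StateKind, states_for_period
from .survival import SurvivalFit, daily_transition_probs

__all__ = [
    "AdjustmentSpec",
    "TransitionSchedule",
    "CohortTrace",
    "ScheduleInputs",
    "build_schedule",
    "apply_mortality_adjustment",
    "apply_los_adjustment",
    "run_cohort",
    "reduce_ward_mean_los",
]

DEFAULT_COHORT_SIZE = 6438  # hypothetical annual London stroke cohort


@dataclass(frozen=True)
class AdjustmentSpec:
    """National-trend adjustments applied to the 'before' arm.

    mortality_pp_at_30d: cumulative 30-day deaths reduced by this many
    percentage points of the cohort (national audit trend 20.7% -> 18.3%).
    su_los_reduction_days: mean stroke-unit stay reduced by this many days
    (national trend 23.1 -> 18.1 days).
    """

    mortality_pp_at_30d: float = 2.4
    su_los_reduction_days: float = 5.0
    adjust_mortality: bool = True
    adjust_los: bool = True
    mortality_mode: str = "rescale"  # rescale (days 0-29) | day30 (day-29 flow only)

    def __post_init__(self) -> None:
        if self.mortality_pp_at_30d < 0:
            raise ValueError("mortality_pp_at_30d must be >= 0")
        if self.su_los_reduction_days < 0:
            raise ValueError("su_los_reduction_days must be >= 0")
        if self.mortality_mode not in ("rescale", "day30"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")


@dataclass(frozen=True)
class ScheduleInputs:
    """Everything needed to (re)build a schedule; kept as provenance."""

    death_fit: SurvivalFit
    exit_fits: dict[str, SurvivalFit]
    destinations: dict[str, dict[str, float]]  # ward -> state name -> prob
    initial: dict[str, float]  # first-ward occupancy fractions
    period: str
    n_days: int = 90


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-day row-stochastic matrices over the period's state list."""

    states: tuple[str, ...]
    matrices: np.ndarray  # (n_days, n_states, n_states)
    initial: np.ndarray  # fractions over states, sums to 1
    inputs: ScheduleInputs | None = None

    @property
    def n_days(self) -> int:
        return self.matrices.shape[0]

    def index(self, state: str) -> int:
        return self.states.index(state)

    def validate(self, atol: float = 1e-9) -> None:
        m = self.matrices
        if np.any(m < -atol):
            raise ValueError("negative transition probability")
        row_sums = m.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=atol):
            raise ValueError("transition matrix rows do not sum to 1")
        dead = self.index("DEAD")
        unit = np.zeros(len(self.states))
        unit[dead] = 1.0
        if not np.allclose(m[:, dead, :], unit, atol=atol):
            raise ValueError("DEAD row is not the unit vector")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution does not sum to 1")


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy counts per cycle (row 0 = initial distribution)."""

    states: tuple[str, ...]
    occupancy: np.ndarray  # (n_cycles + 1, n_states), persons
    cohort_size: float
    cycle_days: float = 1.0

    def state_series(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return self.cohort_size - self.state_series("DEAD")


def _compose_competing(p_risks: np.ndarray) -> tuple[float, np.ndarray]:
    """Total exit probability and per-risk allocation from marginal daily
    probabilities, composed on the rate scale (order-independent)."""
    p = np.clip(p_risks, 0.0, 1.0)
    if np.any(p >= 1.0):
        # a certain risk absorbs everything, split evenly among certain risks
        total = 1.0
        alloc = np.where(p >= 1.0, 1.0, 0.0)
        return total, alloc / alloc.sum()
    rates = -np.log1p(-p)
    rsum = rates.sum()
    if rsum <= 0.0:
        return 0.0, np.zeros_like(p)
    total = -np.expm1(-rsum)
    return total, rates / rsum


def build_schedule(inputs: ScheduleInputs) -> TransitionSchedule:
    """Assemble the per-day transition matrices from the fitted hazards.

    Every alive state faces the period death hazard; inpatient wards
    additionally face their exit hazard, with exiting mass split by the
    ward's destination mixture. A ward reachable in the period's state
    graph without an exit fit is a configuration error.
    """
    states = tuple(states_for_period(inputs.period))
    n = len(states)
    idx = {s: i for i, s in enumerate(states)}
    dead = idx["DEAD"]

    reachable_wards = set(inputs.initial) | {
        tgt for mix in inputs.destinations.values() for tgt in mix
        if STATE_KIND.get(tgt) is StateKind.INPATIENT
    }
    missing = sorted(w for w in reachable_wards if w not in inputs.exit_fits)
    if missing:
        raise ValueError(f"no exit fit for reachable ward(s): {missing}")
    missing_mix = sorted(w for w in reachable_wards if w not in inputs.destinations)
    if missing_mix:
        raise ValueError(f"no destination mixture for ward(s): {missing_mix}")

    p_death = daily_transition_probs(inputs.death_fit, inputs.n_days)
    p_exit = {w: daily_transition_probs(f, inputs.n_days) for w, f in inputs.exit_fits.items()}

    mats = np.zeros((inputs.n_days, n, n))
    for t in range(inputs.n_days):
        m = mats[t]
        m[dead, dead] = 1.0
        for s in states:
            i = idx[s]
            if s == "DEAD":
                continue
            kind = STATE_KIND[s]
            if kind is StateKind.INPATIENT and s in reachable_wards:
                total, alloc = _compose_competing(np.array([p_death[t], p_exit[s][t]]))
                m[i, i] = 1.0 - total
                m[i, dead] += total * alloc[0]
                exit_mass = total * alloc[1]
                for tgt, w in inputs.destinations[s].items():
                    if tgt == s:
                        m[i, i] += exit_mass * w
                    else:
                        m[i, idx[tgt]] += exit_mass * w
            else:
                # discharged states (and unseeded wards): death is the only exit
                m[i, i] = 1.0 - p_death[t]
                m[i, dead] += p_death[t]

    initial = np.zeros(n)
    for w, p in inputs.initial.items():
        initial[idx[w]] = p
    sched = TransitionSchedule(states=states, matrices=mats, initial=initial, inputs=inputs)
    sched.validate()
    return sched


def run_cohort(schedule: TransitionSchedule, cohort_size: float = DEFAULT_COHORT_SIZE) -> CohortTrace:
    """Propagate the cohort through the schedule (matrix-vector products).

    Conservation and DEAD monotonicity are asserted every cycle.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be > 0")
    schedule.validate()
    n_days = schedule.n_days
    occ = np.zeros((n_days + 1, len(schedule.states)))
    occ[0] = schedule.initial * cohort_size
    dead = schedule.index("DEAD")
    for t in range(n_days):
        occ[t + 1] = occ[t] @ schedule.matrices[t]
        if abs(occ[t + 1].sum() - cohort_size) > 1e-6 * max(cohort_size, 1.0):
            raise AssertionError(f"cohort not conserved at cycle {t + 1}")
        if occ[t + 1, dead] < occ[t, dead] - 1e-9 * cohort_size:
            raise AssertionError(f"DEAD occupancy decreased at cycle {t + 1}")
    return CohortTrace(states=schedule.states, occupancy=occ, cohort_size=float(cohort_size))


def _cumulative_dead_fraction(schedule: TransitionSchedule, cycle: int,
                              matrices: np.ndarray | None = None) -> float:
    m = schedule.matrices if matrices is None else matrices
    occ = schedule.initial.copy()
    for t in range(cycle):
        occ = occ @ m[t]
    return float(occ[schedule.index("DEAD")])


def _scaled_matrices(schedule: TransitionSchedule, factor: float, days) -> np.ndarray:
    """Scale into-DEAD entries on the given days by ``factor``; freed
    probability mass returns to each source state's diagonal."""
    m = schedule.matrices.copy()
    dead = schedule.index("DEAD")
    for t in days:
        freed = (1.0 - factor) * m[t, :, dead]
        freed[dead] = 0.0  # DEAD row untouched
        m[t, :, dead] -= freed
        m[t][np.arange(m.shape[1]), np.arange(m.shape[1])] += freed
    return m


def apply_mortality_adjustment(schedule: TransitionSchedule, pp: float,
                               mode: str = "rescale") -> TransitionSchedule:
    """Reduce cumulative 30-day deaths by ``pp`` percentage points of the cohort.

    mode='rescale' (default) scales every into-DEAD entry over days 0-29 by a
    single factor found by bisection against the cohort trace, preserving the
    hazard shape; mode='day30' concentrates the whole reduction in the day-29
    transition (a literal "subtract deaths at 30 days" reading). Hazards from
    day 30 on are unchanged either way.
    """
    if pp == 0.0:
        return schedule
    if pp < 0:
        raise ValueError("pp must be >= 0")
    target_drop = pp / 100.0
    base = _cumulative_dead_fraction(schedule, 30)
    target = base - target_drop
    days = range(30) if mode == "rescale" else [29]
    floor = _cumulative_dead_fraction(schedule, 30, _scaled_matrices(schedule, 0.0, days))
    if target < floor - 1e-12 or target < 0:
        raise ValueError(
            f"mortality adjustment of {pp}pp infeasible: baseline 30-day deaths "
            f"{base * 100:.2f}%, minimum attainable {floor * 100:.2f}%"
        )

    lo, hi = 0.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = _cumulative_dead_fraction(schedule, 30, _scaled_matrices(schedule, mid, days))
        if val > target:
            hi = mid
        else:
            lo = mid
    factor = 0.5 * (lo + hi)
    out = replace(schedule, matrices=_scaled_matrices(schedule, factor, days))
    out.validate()
    return out


def reduce_ward_mean_los(fit: SurvivalFit, days: float) -> SurvivalFit:
    """Rescale a ward-exit Weibull so its implied mean stay drops by ``days``.

    Mean stay is scale * Gamma(1 + 1/shape), linear in the scale for fixed
    shape, so the scale shrinks by the factor (mean - days) / mean.
    """
    mean = fit.mean()
    new_mean = mean - days
    if new_mean <= 0:
        raise ValueError(f"LOS reduction {days} >= current mean stay {mean:.2f}")
    return fit.with_scale(fit.scale * new_mean / mean)


def apply_los_adjustment(schedule: TransitionSchedule, days: float,
                         wards: tuple[str, ...] = ("ASU",)) -> TransitionSchedule:
    """Rebuild the schedule with the stroke-unit mean stay reduced by ``days``."""
    if days == 0.0:
        return schedule
    if schedule.inputs is None:
        raise ValueError("schedule carries no provenance inputs; cannot rebuild")
    exit_fits = dict(schedule.inputs.exit_fits)
    for w in wards:
        if w in exit_fits:
            exit_fits[w] = reduce_ward_mean_los(exit_fits[w], days)
    return build_schedule(replace(schedule.inputs, exit_fits=exit_fits))


def apply_adjustments(schedule: TransitionSchedule, spec: AdjustmentSpec,
                      period: str) -> TransitionSchedule:
    """Apply the national-trend adjustments; no-op for the 'after' arm."""
    if period != "before":
        return schedule
    out = schedule
    if spec.adjust_los and spec.su_los_reduction_days > 0:
        out = apply_los_adjustment(out, spec.su_los_reduction_days)
    if spec.adjust_mortality and spec.mortality_pp_at_30d > 0:
        out = apply_mortality_adjustment(out, spec.mortality_pp_at_30d, spec.mortality_mode)
    return out
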