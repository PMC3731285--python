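"""End-to-end assembly: register -> fits -> schedules -> traces -> economics.

This is the glue the command-line interface, the scenario battery and the
probabilistic sensitivity analysis all share. One period's register yields a
``PeriodFits`` bundle (death fit, per-ward exit fits, destination mixtures,
first-ward distribution, Barthel summaries); a pair of bundles plus cost and
utility configuration yields the before/after comparison at 90 days and 10
years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .econ import (
    ArmResult,
    CostSchedule,
    EconResult,
    UtilityMap,
    accrue,
    combine_horizons,
    compare,
    default_cost_schedule,
    default_long_run_utilities,
    default_state_utilities,
)
from .markov_long import (
    DiscountSpec,
    LongRunTransitions,
    default_barthel_mixture,
    default_long_run_transitions,
    run_long_cohort,
    seed_from_short_run,
)
from .markov_short import (
    DEFAULT_COHORT_SIZE,
    AdjustmentSpec,
    CohortTrace,
    ScheduleInputs,
    TransitionSchedule,
    apply_adjustments,
    build_schedule,
    run_cohort,
)
from .states import barthel_band
from .survival import CoxFit, KMCurve, SurvivalFit, fit_cox, fit_weibull, km_estimate
from .synthetic_data import DEST_TO_STATE, PatientRecord

__all__ = [
    "PeriodFits",
    "AnalysisInputs",
    "ArmOutputs",
    "AnalysisResult",
    "fit_period",
    "death_km",
    "period_hazard_ratio",
    "build_arm_schedule",
    "run_arm",
    "run_analysis",
]


@dataclass(frozen=True)
class PeriodFits:
    """Everything the cohort model needs from one period's register."""

    period: str
    n: int
    death_fit: SurvivalFit
    exit_fits: dict[str, SurvivalFit]
    destination_counts: dict[str, dict[str, float]]  # ward -> next state -> count
    initial_counts: dict[str, float]  # first ward -> count
    barthel_admission_mean: float
    barthel_90d_mean: float
    barthel_mixture: dict[str, float]  # home-band mixture at 90 days
    thrombolysis_rate: float

    def destination_probs(self) -> dict[str, dict[str, float]]:
        out = {}
        for ward, counts in self.destination_counts.items():
            total = sum(counts.values())
            if total <= 0:
                raise ValueError(f"ward {ward}: no observed live exits")
            out[ward] = {tgt: c / total for tgt, c in counts.items()}
        return out

    def initial_probs(self) -> dict[str, float]:
        total = sum(self.initial_counts.values())
        return {w: c / total for w, c in self.initial_counts.items()}


def _death_times(records: list[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.death_day if r.death_day is not None else r.censor_day
                      for r in records], dtype=float)
    events = np.array([r.death_day is not None for r in records])
    return times, events


def _zero_hazard_fit(n: int, period: str, ward: str) -> SurvivalFit:
    """Degenerate exit fit for a ward with no observed live exits."""
    params = np.array([0.0, np.log(1e9)])
    return SurvivalFit(
        family="exponential", shape=1.0, scale=1e9, coefficients={},
        params=params, covariance=np.zeros((2, 2)),
        param_names=("log_shape", "log_scale"), log_likelihood=0.0,
        n=n, n_events=0, period=period, transition=f"exit:{ward}:zero-hazard",
    )


def death_km(records: list[PatientRecord]) -> KMCurve:
    """Kaplan-Meier curve of all-cause death from admission."""
    times, events = _death_times(records)
    return km_estimate(times, events)


def fit_period(records: list[PatientRecord], period: str | None = None) -> PeriodFits:
    """Fit all transition ingredients from one period's register."""
    if not records:
        raise ValueError("empty register")
    period = period or records[0].period
    if any(r.period != period for r in records):
        raise ValueError("register mixes periods")

    times, events = _death_times(records)
    death_fit = fit_weibull(times, events, period=period, transition="death")

    # ward sojourns: event = left the ward alive; censored if died there or
    # follow-up ended in the ward
    durations: dict[str, list[float]] = {}
    exit_events: dict[str, list[bool]] = {}
    dest_counts: dict[str, dict[str, float]] = {}
    initial_counts: dict[str, float] = {}
    for rec in records:
        eps = rec.ward_episodes
        initial_counts[eps[0][0]] = initial_counts.get(eps[0][0], 0) + 1
        for i, (ward, entry, exit_) in enumerate(eps):
            last = i == len(eps) - 1
            left_alive = (not last) or rec.discharge_destination != "none"
            durations.setdefault(ward, []).append(float(exit_ - entry))
            exit_events.setdefault(ward, []).append(left_alive)
            if left_alive:
                nxt = eps[i + 1][0] if not last else DEST_TO_STATE[rec.discharge_destination]
                dest_counts.setdefault(ward, {})[nxt] = dest_counts.setdefault(ward, {}).get(nxt, 0) + 1

    exit_fits = {}
    for ward, durs in durations.items():
        n_exit = sum(exit_events[ward])
        if n_exit == 0:
            # no live exit observed: the MLE limit is a zero exit hazard,
            # so ward occupants leave only through death
            exit_fits[ward] = _zero_hazard_fit(len(durs), period, ward)
            dest_counts.setdefault(ward, {"HOME": 1.0})
        elif n_exit < 5:
            # too sparse for a free shape; exponential sojourn
            exit_fits[ward] = fit_weibull(durs, exit_events[ward], fix_shape=1.0,
                                          period=period, transition=f"exit:{ward}")
        else:
            exit_fits[ward] = fit_weibull(durs, exit_events[ward], period=period,
                                          transition=f"exit:{ward}")

    bi_adm = float(np.mean([r.barthel_admission for r in records]))
    bi90 = [r.barthel_90d for r in records if r.barthel_90d is not None]
    bi90_mean = float(np.mean(bi90)) if bi90 else bi_adm
    home90 = [r.barthel_90d for r in records
              if r.barthel_90d is not None and r.discharge_destination in ("home", "home_with_ESD")]
    if len(home90) >= 10:
        counts = {"HOME_INDEPENDENT": 0, "HOME_MODERATE": 0, "HOME_DEPENDENT": 0}
        for b in home90:
            counts[barthel_band(b)] += 1
        total = sum(counts.values())
        mixture = {k: v / total for k, v in counts.items()}
    else:
        mixture = default_barthel_mixture(bi90_mean, 6.0)

    return PeriodFits(
        period=period,
        n=len(records),
        death_fit=death_fit,
        exit_fits=exit_fits,
        destination_counts=dest_counts,
        initial_counts=initial_counts,
        barthel_admission_mean=bi_adm,
        barthel_90d_mean=bi90_mean,
        barthel_mixture=mixture,
        thrombolysis_rate=float(np.mean([r.thrombolysis for r in records])),
    )


def period_hazard_ratio(before: list[PatientRecord], after: list[PatientRecord]) -> CoxFit:
    """Age-adjusted Cox contrast of the two periods (after vs before)."""
    pooled = list(before) + list(after)
    times, events = _death_times(pooled)
    covariates = pd.DataFrame({
        "period_after": [1.0 if r.period == "after" else 0.0 for r in pooled],
        "age": [r.age for r in pooled],
    })
    return fit_cox(times, events, covariates)


@dataclass(frozen=True)
class AnalysisInputs:
    """Point-estimate bundle for the deterministic run, scenarios and PSA."""

    fits_before: PeriodFits
    fits_after: PeriodFits
    costs: CostSchedule = field(default_factory=default_cost_schedule)
    utility_map: UtilityMap = field(default_factory=UtilityMap)
    adjustments: AdjustmentSpec = field(default_factory=AdjustmentSpec)
    long_transitions: LongRunTransitions = field(default_factory=default_long_run_transitions)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    cohort_size: float = DEFAULT_COHORT_SIZE
    inpatient_rule: str = "institutional"
    n_days: int = 90
    fits_after_alt: PeriodFits | None = None  # restricted 'after' data sources


@dataclass(frozen=True)
class ArmOutputs:
    period: str
    schedule: TransitionSchedule
    trace_short: CohortTrace
    trace_long: CohortTrace
    arm_90d: ArmResult
    arm_10y: ArmResult

    def survival_90d(self) -> float:
        return float(self.trace_short.alive()[-1] / self.trace_short.cohort_size)


@dataclass(frozen=True)
class AnalysisResult:
    before: ArmOutputs
    after: ArmOutputs
    econ_90d: EconResult
    econ_10y: EconResult


def build_arm_schedule(fits: PeriodFits, adjustments: AdjustmentSpec | None = None,
                       n_days: int = 90) -> TransitionSchedule:
    """Point-estimate schedule for one arm, trend-adjusted if 'before'."""
    sched = build_schedule(ScheduleInputs(
        death_fit=fits.death_fit,
        exit_fits=fits.exit_fits,
        destinations=fits.destination_probs(),
        initial=fits.initial_probs(),
        period=fits.period,
        n_days=n_days,
    ))
    if adjustments is not None:
        sched = apply_adjustments(sched, adjustments, fits.period)
    return sched


def run_arm(fits: PeriodFits, inputs: AnalysisInputs,
            schedule: TransitionSchedule | None = None) -> ArmOutputs:
    """Run one arm through both horizons and accrue costs and QALYs."""
    period = fits.period
    if schedule is None:
        schedule = build_arm_schedule(fits, inputs.adjustments, inputs.n_days)
    trace = run_cohort(schedule, inputs.cohort_size)

    utilities = default_state_utilities(
        period, inputs.utility_map,
        bi_admission_mean=fits.barthel_admission_mean,
        bi_90d_mean=fits.barthel_90d_mean,
    )
    costs = inputs.costs
    if "thrombolysis" in costs.one_off:
        ev = costs.one_off["thrombolysis"]
        prob = dict(ev.prob)
        prob[period] = fits.thrombolysis_rate
        costs = replace(costs, one_off={**costs.one_off, "thrombolysis": replace(ev, prob=prob)})

    arm_90d = accrue(trace, costs, utilities, discount=None, period=period,
                     include_one_off=True)

    initial_long = seed_from_short_run(trace, fits.barthel_mixture, inputs.inpatient_rule)
    trace_long = run_long_cohort(initial_long, inputs.long_transitions)
    long_utils = default_long_run_utilities(inputs.utility_map)
    arm_long = accrue(trace_long, costs, long_utils, discount=inputs.discount,
                      period=period, day_offset=90.0)
    arm_10y = combine_horizons(arm_90d, arm_long)
    return ArmOutputs(period=period, schedule=schedule, trace_short=trace,
                      trace_long=trace_long, arm_90d=arm_90d, arm_10y=arm_10y)


def run_analysis(inputs: AnalysisInputs, use_alt_after: bool = False) -> AnalysisResult:
    """Deterministic before/after comparison at both horizons."""
    fits_after = inputs.fits_after
    if use_alt_after:
        if inputs.fits_after_alt is None:
            raise ValueError("no restricted 'after' fits provided")
        fits_after = inputs.fits_after_alt
    before = run_arm(inputs.fits_before, inputs)
    after = run_arm(fits_after, inputs)
    return AnalysisResult(
        before=before,
        after=after,
        econ_90d=compare(before.arm_90d, after.arm_90d),
        econ_10y=compare(before.arm_10y, after.arm_10y),
    )
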