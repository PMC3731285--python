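"""Costs, utilities and incremental cost-effectiveness.

Costing takes an English NHS + Personal Social Services (PSS) perspective in
2010/11 UK pounds; an NHS-only perspective drops the items flagged as PSS
(institutional/nursing-home care). Ward states carry a cost per bed-day;
long-run states a cost per 90-day cycle; one-off events (ambulance
conveyance, imaging, interventions, thrombolysis) are costed as expected
values at admission: per-period event probability x unit cost x cohort.

Utilities come from the Barthel index through a configurable map. The
default is the affine calibration u = 0.05*BI - 0.235 (clipped to
[-0.235, 1]), which passes through the two published (mean Barthel, mean
utility) anchor pairs, (9.3, 0.23) and (10.7, 0.30). It is a calibration
stand-in, not the published mapping algorithm.

All unit-cost defaults are assumptions (the study's unit-cost table is not
reproduced here); they are plain data easily overridden in config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .markov_long import DiscountSpec, discount_factor
from .markov_short import CohortTrace

__all__ = [
    "CostItem",
    "OneOffEvent",
    "CostSchedule",
    "UtilityMap",
    "barthel_to_utility",
    "ArmResult",
    "EconResult",
    "accrue",
    "combine_horizons",
    "compare",
    "default_cost_schedule",
    "default_state_utilities",
]

PERSPECTIVES = ("NHS+PSS", "NHS-only")


@dataclass(frozen=True)
class CostItem:
    amount: float  # 2010/11 UK pounds
    pss: bool = False  # True: Personal Social Services (dropped under NHS-only)

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("costs must be >= 0")


@dataclass(frozen=True)
class OneOffEvent:
    unit_cost: float
    prob: dict[str, float]  # period -> probability
    pss: bool = False

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be >= 0")
        for period, p in self.prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {period!r} outside [0, 1]")


@dataclass(frozen=True)
class CostSchedule:
    """Per-state and one-off costs under a stated perspective."""

    daily: dict[str, CostItem]  # short-run states, per bed-day
    per_cycle: dict[str, CostItem]  # long-run states, per 90-day cycle
    one_off: dict[str, OneOffEvent]
    perspective: str = "NHS+PSS"

    def __post_init__(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")

    def _amount(self, item: CostItem | OneOffEvent, value: float) -> float:
        if item.pss and self.perspective == "NHS-only":
            return 0.0
        return value

    def daily_cost(self, state: str) -> float:
        item = self.daily[state]
        return self._amount(item, item.amount)

    def cycle_cost(self, state: str) -> float:
        item = self.per_cycle[state]
        return self._amount(item, item.amount)

    def one_off_expected(self, period: str) -> float:
        """Expected one-off cost per patient for the period."""
        total = 0.0
        for ev in self.one_off.values():
            p = ev.prob.get(period, 0.0)
            total += self._amount(ev, p * ev.unit_cost)
        return total

    def scaled(self, state_factor: dict[str, float]) -> "CostSchedule":
        """New schedule with named short-run states' daily costs scaled."""
        daily = {
            s: replace(item, amount=item.amount * state_factor.get(s, 1.0))
            for s, item in self.daily.items()
        }
        return replace(self, daily=daily)


def default_cost_schedule() -> CostSchedule:
    """Assumption defaults for 2010/11 UK unit costs (editable config)."""
    daily = {
        "HASU": CostItem(600.0),  # enhanced hyper-acute tariff
        "ASU": CostItem(350.0),
        "SU": CostItem(350.0),
        "STROKE_REHAB": CostItem(250.0),
        "MEDICAL": CostItem(300.0),
        "SURGICAL": CostItem(350.0),
        "ICU": CostItem(1200.0),
        "HOME": CostItem(5.0),  # residual community contacts
        "HOME_ESD": CostItem(45.0),  # early-supported-discharge team
        "NURSING_HOME": CostItem(110.0, pss=True),
        "DEAD": CostItem(0.0),
    }
    per_cycle = {
        "HOME_INDEPENDENT": CostItem(300.0),
        "HOME_MODERATE": CostItem(900.0),
        "HOME_DEPENDENT": CostItem(2200.0),
        "INSTITUTIONAL_CARE": CostItem(9000.0, pss=True),
        "DEAD": CostItem(0.0),
    }
    one_off = {
        "ambulance": OneOffEvent(250.0, {"before": 1.0, "after": 1.0}),
        "ct_head": OneOffEvent(100.0, {"before": 0.95, "after": 0.94}),
        "mri_head": OneOffEvent(250.0, {"before": 0.51, "after": 0.68}),
        "ct_angiography": OneOffEvent(150.0, {"before": 0.40, "after": 0.63}),
        "echocardiogram": OneOffEvent(100.0, {"before": 0.28, "after": 0.49}),
        "carotid_stenting": OneOffEvent(3000.0, {"before": 0.11, "after": 0.14}),
        "neurosurgery": OneOffEvent(8000.0, {"before": 0.06, "after": 0.01}),
        "thrombolysis": OneOffEvent(600.0, {"before": 0.05, "after": 0.13}),
    }
    return CostSchedule(daily=daily, per_cycle=per_cycle, one_off=one_off)


@dataclass(frozen=True)
class UtilityMap:
    """Barthel (0-20) to utility. Affine form u = slope*BI + intercept,
    clipped; or an explicit 21-entry lookup table. Must be monotone
    non-decreasing with utility <= 1."""

    form: str = "affine"  # affine | table
    slope: float = 0.05
    intercept: float = -0.235
    table: tuple[float, ...] = ()
    clip_low: float = -0.235
    clip_high: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("affine", "table"):
            raise ValueError(f"unknown utility map form {self.form!r}")
        if self.form == "affine":
            if self.slope < 0:
                raise ValueError("affine utility map must be non-decreasing (slope >= 0)")
        else:
            if len(self.table) != 21:
                raise ValueError("lookup table needs 21 entries (Barthel 0-20)")
            if any(b < a for a, b in zip(self.table, self.table[1:])):
                raise ValueError("utility table must be monotone non-decreasing")
            if max(self.table) > 1.0:
                raise ValueError("utility cannot exceed 1")
        if self.clip_high > 1.0:
            raise ValueError("utility cannot exceed 1")


def barthel_to_utility(score: float, umap: UtilityMap | None = None) -> float:
    """Utility for a Barthel score under the map (default affine calibration)."""
    umap = umap or UtilityMap()
    if not 0 <= score <= 20:
        raise ValueError(f"Barthel score {score} outside [0, 20]")
    if umap.form == "table":
        return float(umap.table[int(round(score))])
    u = umap.slope * score + umap.intercept
    return float(np.clip(u, umap.clip_low, umap.clip_high))


def default_state_utilities(period: str, umap: UtilityMap | None = None,
                            bi_admission_mean: float | None = None,
                            bi_90d_mean: float | None = None) -> dict[str, float]:
    """Per-state utilities for the short-run model (assumption defaults).

    Inpatients carry the period's mean admission-Barthel utility; home
    states the improved 90-day Barthel utility; nursing-home residents a
    low-Barthel utility.
    """
    umap = umap or UtilityMap()
    if bi_admission_mean is None:
        bi_admission_mean = 9.3 if period == "before" else 10.7
    if bi_90d_mean is None:
        bi_90d_mean = bi_admission_mean + (3.0 if period == "before" else 4.0)
    u_in = barthel_to_utility(min(bi_admission_mean, 20), umap)
    u_home = barthel_to_utility(min(bi_90d_mean, 20), umap)
    u_nh = barthel_to_utility(4.0, umap)
    out = {s: u_in for s in ("HASU", "ASU", "SU", "STROKE_REHAB", "MEDICAL", "SURGICAL", "ICU")}
    out.update({"HOME": u_home, "HOME_ESD": u_home, "NURSING_HOME": u_nh, "DEAD": 0.0})
    return out


def default_long_run_utilities(umap: UtilityMap | None = None) -> dict[str, float]:
    """Long-run state utilities from band-midpoint Barthel scores."""
    umap = umap or UtilityMap()
    return {
        "HOME_INDEPENDENT": barthel_to_utility(17.5, umap),
        "HOME_MODERATE": barthel_to_utility(12.0, umap),
        "HOME_DEPENDENT": barthel_to_utility(4.5, umap),
        "INSTITUTIONAL_CARE": barthel_to_utility(3.0, umap),
        "DEAD": 0.0,
    }


@dataclass(frozen=True)
class ArmResult:
    """Accrued totals for one arm over one horizon."""

    period: str
    horizon_days: float
    cohort_size: float
    total_cost: float
    total_qalys: float
    deaths: float

    def per_patient_cost(self) -> float:
        return self.total_cost / self.cohort_size


def accrue(trace: CohortTrace, costs: CostSchedule, utilities: dict[str, float],
           discount: DiscountSpec | None = None, period: str = "",
           day_offset: float = 0.0, include_one_off: bool = False) -> ArmResult:
    """Accrue costs and QALYs over a trace.

    Occupancy at the start of each cycle accrues that cycle's cost and
    utility-weighted time, discounted at the mid-cycle day (day_offset
    shifts the clock for the long-run model, which starts at day 90).
    One-off admission events are added only when ``include_one_off`` (the
    short-run arm).
    """
    missing = [s for s in trace.states if s not in utilities]
    if missing:
        raise ValueError(f"no utility configured for state(s): {missing}")
    cost_lookup = costs.daily_cost if trace.cycle_days == 1.0 else costs.cycle_cost
    try:
        unit = np.array([cost_lookup(s) for s in trace.states])
    except KeyError as exc:
        raise ValueError(f"no cost configured for state {exc.args[0]!r}") from exc
    util = np.array([utilities[s] for s in trace.states])

    n_cycles = trace.n_cycles
    occ = trace.occupancy[:-1]  # state during each cycle
    mid_days = day_offset + (np.arange(n_cycles) + 0.5) * trace.cycle_days
    df = np.ones(n_cycles)
    if discount is not None:
        df = np.array([discount_factor(discount, d) for d in mid_days])

    # unit costs are already per cycle (per bed-day short-run, per 90-day
    # cycle long-run), so no extra cycle-length factor on the cost side
    total_cost = float(np.sum((occ @ unit) * df))
    total_qalys = float(np.sum((occ @ util) * df) * trace.cycle_days / 365.25)
    if include_one_off:
        if not period:
            raise ValueError("period required to cost one-off admission events")
        total_cost += costs.one_off_expected(period) * trace.cohort_size
    deaths = float(trace.occupancy[-1, trace.states.index("DEAD")]
                   - trace.occupancy[0, trace.states.index("DEAD")])
    return ArmResult(period=period, horizon_days=day_offset + n_cycles * trace.cycle_days,
                     cohort_size=trace.cohort_size, total_cost=total_cost,
                     total_qalys=total_qalys, deaths=deaths)


def combine_horizons(short: ArmResult, long: ArmResult) -> ArmResult:
    """Sum the 90-day and 90-day-to-10-year accruals for one arm."""
    if short.period != long.period:
        raise ValueError("cannot combine arms from different periods")
    return ArmResult(
        period=short.period,
        horizon_days=long.horizon_days,
        cohort_size=short.cohort_size,
        total_cost=short.total_cost + long.total_cost,
        total_qalys=short.total_qalys + long.total_qalys,
        deaths=short.deaths + long.deaths,
    )


@dataclass(frozen=True)
class EconResult:
    """After-minus-before increments with ICERs and the dominance label.

    Dominance follows the published footnote rule: 'Dominant' means costs
    are lower and either deaths are lower or QALYs are higher. ICERs are
    reported only in the trade-off quadrants; otherwise None.
    """

    horizon_days: float
    cohort_size: float
    cost_before: float
    cost_after: float
    delta_cost: float
    delta_deaths: float
    delta_qalys: float
    icer_per_death_averted: float | None
    icer_per_qaly: float | None
    dominance: str  # dominant | dominated | trade-off

    def per_patient_delta_cost(self) -> float:
        return self.delta_cost / self.cohort_size


def _dominance(d_cost: float, d_deaths: float, d_qalys: float) -> str:
    if d_cost < 0 and (d_deaths < 0 or d_qalys > 0):
        return "dominant"
    if d_cost > 0 and d_qalys < 0 and d_deaths >= 0:
        return "dominated"
    return "trade-off"


def compare(before: ArmResult, after: ArmResult) -> EconResult:
    """Incremental comparison (after minus before) with dominance logic."""
    if before.horizon_days != after.horizon_days:
        raise ValueError("mismatched horizons")
    if abs(before.cohort_size - after.cohort_size) > 1e-6:
        raise ValueError("mismatched cohort sizes")
    d_cost = after.total_cost - before.total_cost
    d_deaths = after.deaths - before.deaths
    d_qalys = after.total_qalys - before.total_qalys
    label = _dominance(d_cost, d_deaths, d_qalys)

    # ICERs only where the comparison is a genuine trade-off: paying more
    # for fewer deaths / more QALYs.
    icer_death = icer_qaly = None
    if label == "trade-off":
        if d_deaths < 0 and d_cost > 0:
            icer_death = d_cost / (-d_deaths)
        if d_qalys > 0 and d_cost > 0:
            icer_qaly = d_cost / d_qalys
    return EconResult(
        horizon_days=before.horizon_days,
        cohort_size=before.cohort_size,
        cost_before=before.total_cost,
        cost_after=after.total_cost,
        delta_cost=d_cost,
        delta_deaths=d_deaths,
        delta_qalys=d_qalys,
        icer_per_death_averted=icer_death,
        icer_per_qaly=icer_qaly,
        dominance=label,
    )
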