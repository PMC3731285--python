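"""Costing, utilities, accrual arithmetic, ICERs and dominance."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecea.econ import (
    ArmResult,
    CostItem,
    CostSchedule,
    OneOffEvent,
    UtilityMap,
    accrue,
    barthel_to_utility,
    compare,
    default_cost_schedule,
)
from strokecea.markov_short import CohortTrace


def _toy_trace(states, occupancy_row, n_cycles, cycle_days=1.0):
    occ = np.repeat(np.asarray(occupancy_row, dtype=float)[None], n_cycles + 1, axis=0)
    return CohortTrace(states=tuple(states), occupancy=occ,
                       cohort_size=float(sum(occupancy_row)), cycle_days=cycle_days)


class TestUtilityMap:
    @pytest.mark.parametrize("bi,expected", [(9.3, 0.23), (10.7, 0.30)])
    def test_affine_map_passes_through_published_anchors(self, bi, expected):
        assert barthel_to_utility(bi) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            barthel_to_utility(21)
        with pytest.raises(ValueError):
            barthel_to_utility(-1)

    def test_non_monotone_table_rejected(self):
        table = tuple(np.linspace(0, 1, 21))
        shuffled = table[:5] + (table[6], table[5]) + table[7:]
        with pytest.raises(ValueError, match="monotone"):
            UtilityMap(form="table", table=shuffled)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=19))
    def test_utility_monotone_in_barthel(self, b):
        assert barthel_to_utility(b) <= barthel_to_utility(b + 1)
        assert barthel_to_utility(b + 1) <= 1.0


class TestAccrue:
    def test_everyone_dead_accrues_nothing(self):
        trace = _toy_trace(["HOME", "DEAD"], [0.0, 6438.0], 90)
        arm = accrue(trace, default_cost_schedule(), {"HOME": 0.6, "DEAD": 0.0},
                     period="before")
        assert arm.total_cost == 0.0
        assert arm.total_qalys == 0.0

    def test_bed_day_arithmetic(self):
        costs = CostSchedule(daily={"MEDICAL": CostItem(50.0), "DEAD": CostItem(0.0)},
                             per_cycle={}, one_off={})
        trace = _toy_trace(["MEDICAL", "DEAD"], [100.0, 0.0], 10)
        arm = accrue(trace, costs, {"MEDICAL": 0.0, "DEAD": 0.0}, period="before")
        assert arm.total_cost == pytest.approx(100 * 10 * 50.0)

    def test_qaly_hand_sum(self):
        trace = _toy_trace(["HOME", "DEAD"], [250.0, 0.0], 90)
        arm = accrue(trace, default_cost_schedule(), {"HOME": 0.8, "DEAD": 0.0},
                     period="after")
        assert arm.total_qalys == pytest.approx(250 * 0.8 * 90 / 365.25, abs=1e-9)

    def test_one_off_events_are_expected_values(self):
        costs = CostSchedule(
            daily={"HOME": CostItem(0.0), "DEAD": CostItem(0.0)}, per_cycle={},
            one_off={"ct_head": OneOffEvent(100.0, {"before": 0.95})},
        )
        trace = _toy_trace(["HOME", "DEAD"], [1000.0, 0.0], 1)
        arm = accrue(trace, costs, {"HOME": 0.0, "DEAD": 0.0}, period="before",
                     include_one_off=True)
        assert arm.total_cost == pytest.approx(1000 * 0.95 * 100.0)

    def test_missing_state_cost_names_the_state(self):
        costs = CostSchedule(daily={"DEAD": CostItem(0.0)}, per_cycle={}, one_off={})
        trace = _toy_trace(["HOME", "DEAD"], [10.0, 0.0], 5)
        with pytest.raises(ValueError, match="HOME"):
            accrue(trace, costs, {"HOME": 0.5, "DEAD": 0.0}, period="before")

    def test_linearity_in_unit_costs(self, fits_before):
        from strokecea.pipeline import build_arm_schedule
        from strokecea.markov_short import run_cohort

        trace = run_cohort(build_arm_schedule(fits_before, adjustments=None), 6438)
        utilities = {s: 0.3 for s in trace.states}
        utilities["DEAD"] = 0.0
        costs = default_cost_schedule()
        doubled = replace(
            costs,
            daily={s: replace(c, amount=2 * c.amount) for s, c in costs.daily.items()},
            one_off={e: replace(ev, unit_cost=2 * ev.unit_cost)
                     for e, ev in costs.one_off.items()},
        )
        a = accrue(trace, costs, utilities, period="before", include_one_off=True)
        b = accrue(trace, doubled, utilities, period="before", include_one_off=True)
        assert b.total_cost == pytest.approx(2 * a.total_cost, rel=1e-12)

    def test_nhs_only_never_exceeds_full_perspective(self, fits_before):
        from strokecea.pipeline import build_arm_schedule
        from strokecea.markov_short import run_cohort

        trace = run_cohort(build_arm_schedule(fits_before, adjustments=None), 6438)
        utilities = {s: 0.3 for s in trace.states}
        costs = default_cost_schedule()
        nhs_only = replace(costs, perspective="NHS-only")
        full = accrue(trace, costs, utilities, period="before", include_one_off=True)
        nhs = accrue(trace, nhs_only, utilities, period="before", include_one_off=True)
        assert nhs.total_cost <= full.total_cost

    def test_additivity_over_disjoint_traces(self):
        costs = default_cost_schedule()
        utilities = {"HOME": 0.7, "NURSING_HOME": 0.1, "DEAD": 0.0}
        t1 = _toy_trace(["HOME", "NURSING_HOME", "DEAD"], [100.0, 0.0, 0.0], 30)
        t2 = _toy_trace(["HOME", "NURSING_HOME", "DEAD"], [0.0, 40.0, 0.0], 30)
        t12 = _toy_trace(["HOME", "NURSING_HOME", "DEAD"], [100.0, 40.0, 0.0], 30)
        a1 = accrue(t1, costs, utilities, period="before")
        a2 = accrue(t2, costs, utilities, period="before")
        a12 = accrue(t12, costs, utilities, period="before")
        assert a12.total_cost == pytest.approx(a1.total_cost + a2.total_cost, rel=1e-12)
        assert a12.total_qalys == pytest.approx(a1.total_qalys + a2.total_qalys, rel=1e-12)


def _arm(cost, qalys, deaths, period, horizon=90.0, n=6438):
    return ArmResult(period=period, horizon_days=horizon, cohort_size=n,
                     total_cost=cost, total_qalys=qalys, deaths=deaths)


class TestCompare:
    def test_identical_arms_have_no_increments_and_no_icer(self):
        a = _arm(1e6, 500.0, 700.0, "before")
        b = _arm(1e6, 500.0, 700.0, "after")
        res = compare(a, b)
        assert res.delta_cost == 0.0
        assert res.icer_per_qaly is None
        assert res.dominance == "trade-off"

    def test_published_icer_arithmetic(self):
        # restricted-data comparison: +£1,898,440 for +33.34 QALYs and
        # 113 fewer deaths at 90 days
        before = _arm(0.0, 0.0, 113.34, "before")
        after = _arm(1_898_440.0, 33.34, 0.0, "after")
        res = compare(before, after)
        assert res.icer_per_qaly == pytest.approx(56_940, rel=0.005)
        assert res.icer_per_death_averted == pytest.approx(16_779, rel=0.005)
        assert res.dominance == "trade-off"

    @pytest.mark.parametrize(
        "d_cost,d_qalys,expected",
        [(-1.0, +1.0, "dominant"), (+1.0, +1.0, "trade-off"),
         (-1.0, -1.0, "trade-off"), (+1.0, -1.0, "dominated")],
    )
    def test_dominance_quadrants(self, d_cost, d_qalys, expected):
        before = _arm(1e6, 100.0, 0.0, "before")
        after = _arm(1e6 + d_cost, 100.0 + d_qalys, 0.0, "after")
        assert compare(before, after).dominance == expected

    def test_dominant_when_cheaper_with_fewer_deaths(self):
        before = _arm(1e6, 100.0, 700.0, "before")
        after = _arm(9e5, 100.0, 650.0, "after")
        res = compare(before, after)
        assert res.dominance == "dominant"
        assert res.icer_per_qaly is None

    def test_mismatched_horizons_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            compare(_arm(0, 0, 0, "before", horizon=90.0),
                    _arm(0, 0, 0, "after", horizon=3652.5))
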