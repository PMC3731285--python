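"""Short-run cohort model: matrix assembly, adjustments, propagation."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from strokecea.markov_short import (
    AdjustmentSpec,
    ScheduleInputs,
    TransitionSchedule,
    apply_adjustments,
    apply_los_adjustment,
    apply_mortality_adjustment,
    build_schedule,
    reduce_ward_mean_los,
    run_cohort,
)
from strokecea.pipeline import build_arm_schedule, death_km
from strokecea.survival import SurvivalFit


def _const_hazard_fit(daily_p: float, transition: str = "death") -> SurvivalFit:
    """Exponential fit with a given constant per-day transition probability."""
    scale = 1e12 if daily_p == 0 else -1.0 / math.log1p(-daily_p)
    return SurvivalFit(family="exponential", shape=1.0, scale=scale, coefficients={},
                       params=np.array([0.0, math.log(scale)]), covariance=np.zeros((2, 2)),
                       param_names=("log_shape", "log_scale"), log_likelihood=0.0,
                       n=1, n_events=1, period="before", transition=transition)


def _toy_schedule(daily_death: float, n_days: int = 90) -> TransitionSchedule:
    """Two states (HOME, DEAD) with a constant daily death probability."""
    m = np.array([[1 - daily_death, daily_death], [0.0, 1.0]])
    return TransitionSchedule(states=("HOME", "DEAD"),
                              matrices=np.repeat(m[None], n_days, axis=0),
                              initial=np.array([1.0, 0.0]))


def _before_inputs(death_p=0.002, exit_p=0.05) -> ScheduleInputs:
    return ScheduleInputs(
        death_fit=_const_hazard_fit(death_p),
        exit_fits={"ASU": _const_hazard_fit(exit_p, "exit:ASU")},
        destinations={"ASU": {"HOME": 1.0}},
        initial={"ASU": 1.0},
        period="before",
    )


class TestBuildSchedule:
    def test_zero_hazards_give_identity(self):
        sched = build_schedule(_before_inputs(death_p=0.0, exit_p=0.0))
        eye = np.eye(len(sched.states))
        assert np.allclose(sched.matrices, eye[None], atol=1e-9)

    def test_single_exit_hazard_row(self):
        p = 0.05
        sched = build_schedule(_before_inputs(death_p=0.0, exit_p=p))
        i, h = sched.index("ASU"), sched.index("HOME")
        row = sched.matrices[0, i]
        assert row[i] == pytest.approx(1 - p, abs=1e-12)
        assert row[h] == pytest.approx(p, abs=1e-12)

    def test_two_competing_risks_closed_form(self):
        sched = build_schedule(_before_inputs(death_p=0.1, exit_p=0.1))
        i = sched.index("ASU")
        row = sched.matrices[0, i]
        total_exit = 1 - row[i]
        assert total_exit == pytest.approx(1 - 0.9 * 0.9, abs=1e-12)
        assert row[sched.index("DEAD")] == pytest.approx(row[sched.index("HOME")], abs=1e-12)

    def test_missing_fit_for_reachable_ward_is_config_error(self):
        inputs = _before_inputs()
        bad = replace(inputs, destinations={"ASU": {"STROKE_REHAB": 1.0}})
        with pytest.raises(ValueError, match="STROKE_REHAB"):
            build_schedule(bad)

    def test_rows_are_stochastic_and_dead_absorbing(self, fits_before):
        sched = build_arm_schedule(fits_before, adjustments=None)
        sched.validate()  # row sums, non-negativity, DEAD unit row


class TestMortalityAdjustment:
    def test_zero_pp_is_identity(self):
        sched = build_schedule(_before_inputs())
        out = apply_mortality_adjustment(sched, 0.0)
        assert out is sched

    def test_toy_chain_hits_exact_30_day_target(self):
        sched = _toy_schedule(0.01)
        base = 1 - 0.99**30
        out = apply_mortality_adjustment(sched, 2.4)
        trace = run_cohort(out, 100.0)
        assert trace.state_series("DEAD")[30] == pytest.approx(base * 100 - 2.4, abs=1e-6)
        # hazards beyond day 30 untouched
        assert np.allclose(out.matrices[30:], sched.matrices[30:])

    def test_day30_mode_concentrates_reduction_on_final_flow(self):
        sched = _toy_schedule(0.01)
        out = apply_mortality_adjustment(sched, 0.5, mode="day30")
        assert np.allclose(out.matrices[:29], sched.matrices[:29])
        trace = run_cohort(out, 100.0)
        assert trace.state_series("DEAD")[30] == pytest.approx((1 - 0.99**30) * 100 - 0.5, abs=1e-6)

    def test_infeasible_reduction_raises(self):
        sched = _toy_schedule(0.0001)  # ~0.3% dead by day 30
        with pytest.raises(ValueError, match="infeasible"):
            apply_mortality_adjustment(sched, 2.4)


class TestLosAdjustment:
    def test_zero_days_is_identity(self, fits_before):
        sched = build_arm_schedule(fits_before, adjustments=None)
        assert apply_los_adjustment(sched, 0.0) is sched

    def test_exponential_mean_rescaling(self):
        # national trend: mean stroke-unit stay 23.1 -> 18.1 days
        fit = _const_hazard_fit(1 - math.exp(-1 / 23.1)).with_scale(23.1)
        out = reduce_ward_mean_los(fit, 5.0)
        assert out.scale == pytest.approx(18.1, abs=1e-9)

    def test_weibull_mean_formula(self):
        from scipy.special import gamma

        fit = replace(_const_hazard_fit(0.01), shape=2.0, scale=20.0)
        mean = 20.0 * gamma(1.5)
        out = reduce_ward_mean_los(fit, 5.0)
        assert out.scale == pytest.approx(20.0 * (mean - 5.0) / mean, abs=1e-12)
        assert out.mean() == pytest.approx(mean - 5.0, abs=1e-9)

    def test_excessive_reduction_raises(self):
        fit = _const_hazard_fit(1 - math.exp(-1 / 4.0)).with_scale(4.0)
        with pytest.raises(ValueError, match="mean"):
            reduce_ward_mean_los(fit, 5.0)

    def test_adjustments_only_touch_before_arm(self, fits_after):
        sched = build_arm_schedule(fits_after, adjustments=None)
        out = apply_adjustments(sched, AdjustmentSpec(), period="after")
        assert out is sched


class TestRunCohort:
    def test_identity_schedule_is_constant(self):
        sched = _toy_schedule(0.0)
        trace = run_cohort(sched, 6438)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_geometric_survival_closed_form(self):
        trace = run_cohort(_toy_schedule(0.1), 6438)
        assert trace.alive()[90] == pytest.approx(6438 * 0.9**90, rel=1e-9)

    def test_conservation_and_dead_monotonicity(self, fits_before):
        sched = build_arm_schedule(fits_before, AdjustmentSpec())
        trace = run_cohort(sched, 6438)
        assert np.allclose(trace.occupancy.sum(axis=1), 6438, atol=1e-6)
        dead = trace.state_series("DEAD")
        assert np.all(np.diff(dead) >= -1e-9)

    def test_model_survival_matches_register_km(self, fits_before, register_before):
        sched = build_arm_schedule(fits_before, adjustments=None)
        trace = run_cohort(sched, 1.0)
        km90 = death_km(register_before).survival_at(90)
        model_s90 = trace.alive()[90]
        # parametric vs product-limit on the same data: sampling tolerance
        assert model_s90 == pytest.approx(km90, abs=0.03)

    def test_after_arm_stroke_units_nearly_empty_at_90_days(self, fits_after):
        sched = build_arm_schedule(fits_after, adjustments=None)
        trace = run_cohort(sched, 6438)
        in_units = trace.state_series("HASU")[90] + trace.state_series("SU")[90]
        assert in_units < 0.01 * 6438


class TestMicrosimOracle:
    def test_trace_matches_walker_microsimulation(self, fits_before):
        from conftest import microsimulate

        sched = build_arm_schedule(fits_before, AdjustmentSpec())
        trace = run_cohort(sched, 1.0)
        n_walk = 20_000
        occ = microsimulate(sched, n_walk, seed=77)
        p = trace.occupancy
        se = np.sqrt(np.clip(p * (1 - p), 0.0, None) / n_walk)
        diff = np.abs(occ / n_walk - p)
        slack = 3.0 / n_walk
        # calibrated per-cell bound: serial correlation clusters excursions
        assert (diff > 3.0 * se + slack).mean() <= 0.01
        assert np.all(diff <= 5.0 * se + slack)
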