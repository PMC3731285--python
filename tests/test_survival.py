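"""Survival estimators against hand calculations and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from strokecea.survival import (
    NonConvergenceError,
    daily_transition_prob,
    daily_transition_probs,
    fit_cox,
    fit_weibull,
    km_estimate,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [True, True, False, True])
        assert list(km.event_times) == [1.0, 2.0, 4.0]
        assert km.survival == pytest.approx([0.75, 0.50, 0.0])
        assert np.all(km.ci_low <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_high + 1e-12)

    def test_all_censored_is_flat_one(self):
        km = km_estimate([5, 10], [False, False])
        assert km.event_times.size == 0
        assert km.survival_at(90) == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [True])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=40))
    def test_uncensored_km_equals_empirical_survival(self, days):
        times = np.asarray(days, dtype=float)
        km = km_estimate(times, np.ones_like(times, dtype=bool))
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)


def _grid_search_weibull(times, shrink=0.2, levels=5):
    """Independent oracle: refine a (shape, scale) grid around the coarse
    likelihood maximizer down to ~1e-4 resolution."""
    t = np.asarray(times, dtype=float)

    def nll(k, lam):
        return -(np.sum(np.log(k / lam) + (k - 1) * np.log(t / lam)) - np.sum((t / lam) ** k))

    k_lo, k_hi, l_lo, l_hi = 0.3, 4.0, t.mean() / 4, t.mean() * 4
    best = None
    for _ in range(levels):
        ks = np.linspace(k_lo, k_hi, 61)
        ls = np.linspace(l_lo, l_hi, 61)
        vals = np.array([[nll(k, lam) for lam in ls] for k in ks])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = (ks[i], ls[j])
        dk, dl = (k_hi - k_lo) * shrink, (l_hi - l_lo) * shrink
        k_lo, k_hi = best[0] - dk, best[0] + dk
        l_lo, l_hi = max(best[1] - dl, 1e-6), best[1] + dl
    return best


class TestWeibullFit:
    def test_exponential_closed_form_uncensored(self):
        fit = fit_weibull([2, 4, 6], [True, True, True], fix_shape=1.0)
        assert fit.family == "exponential"
        assert fit.scale == pytest.approx(4.0, abs=1e-6)

    def test_exponential_closed_form_with_censoring(self):
        # MLE: scale = total time at risk / number of events
        times = [3.0, 7.0, 2.0, 10.0, 5.0]
        events = [True, False, True, False, True]
        fit = fit_weibull(times, events, fix_shape=1.0)
        assert fit.scale == pytest.approx(sum(times) / 3, abs=1e-9)

    def test_recovers_generating_parameters_and_matches_grid_oracle(self):
        rng = np.random.default_rng(1234)
        times = 400.0 * rng.weibull(1.3, 5000)
        fit = fit_weibull(times, np.ones(5000, dtype=bool))
        se_logk = math.sqrt(fit.covariance[0, 0])
        se_logl = math.sqrt(fit.covariance[1, 1])
        assert abs(math.log(fit.shape) - math.log(1.3)) < 3 * se_logk
        assert abs(math.log(fit.scale) - math.log(400.0)) < 3 * se_logl
        k_star, lam_star = _grid_search_weibull(times)
        assert fit.shape == pytest.approx(k_star, abs=1e-3)
        assert fit.scale == pytest.approx(lam_star, rel=1e-3)

    def test_degenerate_all_events_one_instant(self):
        with pytest.raises(NonConvergenceError):
            fit_weibull([5.0] * 20, [True] * 20)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="cannot fit"):
            fit_weibull([1, 2, 3], [False, False, False])

    def test_matches_lifelines_weibull_fitter(self):
        from lifelines import WeibullFitter

        rng = np.random.default_rng(7)
        times = 30.0 * rng.weibull(0.8, 800)
        events = rng.random(800) < 0.8
        censored = np.maximum(np.where(events, times, times * rng.random(800)), 0.5)
        fit = fit_weibull(censored, events)
        wf = WeibullFitter().fit(censored, events)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-4)
        assert fit.scale == pytest.approx(wf.lambda_, rel=1e-4)


def _cox_partial_loglik(beta, times, events, x):
    """Written-out Breslow partial likelihood (no ties in the oracle data)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def test_mirror_groups_give_unit_hazard_ratio(self):
        times = [1, 3, 1, 3]
        events = [True] * 4
        cov = pd.DataFrame({"group": [0, 0, 1, 1]})
        fit = fit_cox(times, events, cov)
        assert fit.hazard_ratios["group"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_partial_likelihood(self):
        times = [1.0, 2.0, 4.0, 5.0, 7.0, 9.0]
        events = [True] * 6
        x = [0, 1, 0, 1, 0, 1]
        fit = fit_cox(times, events, pd.DataFrame({"x": x}))
        res = optimize.minimize_scalar(
            lambda b: -_cox_partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox([1, 2, 3, 4], [True] * 4, pd.DataFrame({"x": [1, 1, 1, 1]}))

    def test_beta_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 120)
        events = rng.random(120) < 0.7
        x = rng.integers(0, 2, 120)
        f1 = fit_cox(times, events, pd.DataFrame({"x": x}))
        f2 = fit_cox(times * 7.3, events, pd.DataFrame({"x": x}))
        assert f1.coefficients["x"] == pytest.approx(f2.coefficients["x"], abs=1e-8)

    def test_reciprocal_hazard_ratio_when_reference_flipped(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, 120)
        events = rng.random(120) < 0.7
        x = rng.integers(0, 2, 120)
        f1 = fit_cox(times, events, pd.DataFrame({"x": x}))
        f2 = fit_cox(times, events, pd.DataFrame({"x": 1 - x}))
        assert f1.hazard_ratios["x"] == pytest.approx(1 / f2.hazard_ratios["x"], rel=1e-6)


class TestDailyTransitionProb:
    def test_exponential_is_memoryless(self):
        fit = fit_weibull([100.0] * 50, [True] * 50, fix_shape=1.0).with_scale(100.0)
        expected = 1 - math.exp(-0.01)
        for day in (0, 1, 17, 89):
            assert daily_transition_prob(fit, day) == pytest.approx(expected, abs=1e-12)

    def test_weibull_closed_form(self):
        from dataclasses import replace

        fit = replace(fit_weibull([1, 2, 3], [True] * 3), shape=2.0, scale=10.0)
        expected = 1 - math.exp(-((0.4**2) - (0.3**2)))
        assert daily_transition_prob(fit, 3) == pytest.approx(expected, abs=1e-12)

    def test_telescoping_product_identity(self, fits_before):
        fit = fits_before.death_fit
        p = daily_transition_probs(fit, 90)
        assert np.all((0 <= p) & (p <= 1))
        prod = np.prod(1 - p)
        expected = fit.survival_function(90.0) / fit.survival_function(0.0)
        assert prod == pytest.approx(float(expected), abs=1e-12)

    def test_negative_day_rejected(self, fits_before):
        with pytest.raises(ValueError):
            daily_transition_prob(fits_before.death_fit, -1)
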