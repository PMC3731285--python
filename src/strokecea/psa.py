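"""Probabilistic sensitivity analysis and the deterministic scenario battery.

The PSA propagates parameter uncertainty through both cohort models with
standard health-economics distribution families (all configurable):

* survival-model parameters: multivariate normal on the (log shape,
  log scale, beta) scale using each fit's observed-information covariance,
  keeping shape and scale positive;
* destination mixtures: Dirichlet with the observed transition counts
  (+1/2 Jeffreys smoothing);
* one-off event probabilities: beta with the period's effective counts;
* unit costs: gamma with mean at the point estimate and a 20% coefficient
  of variation;
* long-run transition rows: Dirichlet around the default row with a fixed
  concentration.

Each draw rebuilds both arms' schedules (re-applying the national-trend
adjustments), runs both horizons, and records the increments. Confidence
intervals are empirical 2.5/97.5 percentiles; the cost-effectiveness
acceptability curve (CEAC) reports, at each willingness-to-pay threshold
lambda, the fraction of draws with positive net monetary benefit
lambda*dQALY - dCost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .econ import EconResult, compare
from .markov_long import LongRunTransitions
from .pipeline import AnalysisInputs, PeriodFits, run_analysis
from .states import LONG_RUN_STATES
from .survival import SurvivalFit

__all__ = [
    "PSASpec",
    "PSAResult",
    "draw_parameters",
    "run_psa",
    "ceac",
    "run_scenarios",
    "SCENARIOS",
    "default_thresholds",
]


@dataclass(frozen=True)
class PSASpec:
    """What to vary, how often, and from which seed."""

    n_draws: int = 10_000
    seed: int = 0
    cost_cv: float = 0.20  # gamma coefficient of variation for unit costs
    dirichlet_smoothing: float = 0.5
    long_run_concentration: float = 200.0
    vary_survival: bool = True
    vary_destinations: bool = True
    vary_event_probs: bool = True
    vary_costs: bool = True
    vary_long_run: bool = True
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if self.cost_cv < 0:
            raise ValueError("cost_cv must be >= 0")
        if self.long_run_concentration <= 0:
            raise ValueError("long_run_concentration must be > 0")

    def frozen(self) -> "PSASpec":
        return replace(self, vary_survival=False, vary_destinations=False,
                       vary_event_probs=False, vary_costs=False, vary_long_run=False)


def _perturb_fit(fit: SurvivalFit, rng: np.random.Generator) -> SurvivalFit:
    # svd factorization: fixed-shape fits carry a singular (PSD) covariance
    draw = rng.multivariate_normal(fit.params, fit.covariance, method="svd")
    shape = float(np.exp(draw[0]))
    scale = float(np.exp(draw[1]))
    coefs = dict(zip(fit.param_names[2:], (float(b) for b in draw[2:])))
    return replace(fit, shape=shape, scale=scale, coefficients=coefs, params=draw)


def _perturb_period(fits: PeriodFits, spec: PSASpec, rng: np.random.Generator) -> PeriodFits:
    out = fits
    if spec.vary_survival:
        out = replace(
            out,
            death_fit=_perturb_fit(fits.death_fit, rng),
            exit_fits={w: _perturb_fit(f, rng) for w, f in fits.exit_fits.items()},
        )
    if spec.vary_destinations:
        new_counts = {}
        for ward, counts in fits.destination_counts.items():
            targets = sorted(counts)
            alpha = np.array([counts[t] + spec.dirichlet_smoothing for t in targets])
            probs = rng.dirichlet(alpha)
            total = sum(counts.values())
            new_counts[ward] = {t: float(p * total) for t, p in zip(targets, probs)}
        out = replace(out, destination_counts=new_counts)
    return out


def _perturb_inputs(inputs: AnalysisInputs, spec: PSASpec,
                    rng: np.random.Generator) -> AnalysisInputs:
    before = _perturb_period(inputs.fits_before, spec, rng)
    after = _perturb_period(inputs.fits_after, spec, rng)
    after_alt = (None if inputs.fits_after_alt is None
                 else _perturb_period(inputs.fits_after_alt, spec, rng))

    costs = inputs.costs
    if spec.vary_costs and spec.cost_cv > 0:
        k = 1.0 / spec.cost_cv**2  # gamma shape from the CV

        def draw_amount(amount: float) -> float:
            if amount <= 0:
                return amount
            return float(rng.gamma(k, amount / k))

        costs = replace(
            costs,
            daily={s: replace(c, amount=draw_amount(c.amount)) for s, c in costs.daily.items()},
            per_cycle={s: replace(c, amount=draw_amount(c.amount))
                       for s, c in costs.per_cycle.items()},
            one_off={e: replace(ev, unit_cost=draw_amount(ev.unit_cost))
                     for e, ev in costs.one_off.items()},
        )
    if spec.vary_event_probs:
        n_eff = {"before": inputs.fits_before.n, "after": inputs.fits_after.n}
        one_off = {}
        for name, ev in costs.one_off.items():
            prob = {}
            for period, p in ev.prob.items():
                n = n_eff.get(period, 100)
                prob[period] = float(rng.beta(p * n + 0.5, (1.0 - p) * n + 0.5))
            one_off[name] = replace(ev, prob=prob)
        costs = replace(costs, one_off=one_off)

    long_tr = inputs.long_transitions
    if spec.vary_long_run:
        mats = long_tr.matrices.copy()
        dead = LONG_RUN_STATES.index("DEAD")
        base = mats[0]
        drawn = base.copy()
        for i in range(base.shape[0]):
            if i == dead:
                continue
            alpha = base[i] * spec.long_run_concentration
            support = alpha > 0
            drawn[i, support] = rng.dirichlet(alpha[support])
            drawn[i, ~support] = 0.0
        mats[:] = drawn[None, :, :]
        long_tr = LongRunTransitions(matrices=mats, source=long_tr.source)

    return replace(inputs, fits_before=before, fits_after=after, fits_after_alt=after_alt,
                   costs=costs, long_transitions=long_tr)


def draw_parameters(inputs: AnalysisInputs, spec: PSASpec) -> list[AnalysisInputs]:
    """The sequence of perturbed input bundles (reproducible given seed)."""
    rng = np.random.default_rng(spec.seed)
    return [_perturb_inputs(inputs, spec, rng) for _ in range(spec.n_draws)]


@dataclass(frozen=True)
class PSAResult:
    """Per-draw increments and their percentile summaries, per horizon."""

    draws: pd.DataFrame  # columns: horizon-prefixed d_cost/d_deaths/d_qalys
    n_failed: int
    point_90d: EconResult
    point_10y: EconResult

    def mean(self, column: str) -> float:
        return float(self.draws[column].mean())

    def ci(self, column: str) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws[column], [2.5, 97.5])
        return float(lo), float(hi)


def run_psa(inputs: AnalysisInputs, spec: PSASpec) -> PSAResult:
    """Monte-Carlo propagation through both models.

    Individual draw failures are excluded and counted; more than
    ``max_failure_fraction`` failing aborts with diagnostics.
    """
    point = run_analysis(inputs)  # the deterministic pipeline must run cleanly
    rng = np.random.default_rng(spec.seed)
    rows = []
    failures: list[str] = []
    for i in range(spec.n_draws):
        drawn = _perturb_inputs(inputs, spec, rng)
        try:
            res = run_analysis(drawn)
        except (ValueError, AssertionError, np.linalg.LinAlgError) as exc:
            failures.append(f"draw {i}: {exc}")
            continue
        rows.append({
            "d_cost_90d": res.econ_90d.delta_cost,
            "d_deaths_90d": res.econ_90d.delta_deaths,
            "d_qalys_90d": res.econ_90d.delta_qalys,
            "d_cost_10y": res.econ_10y.delta_cost,
            "d_deaths_10y": res.econ_10y.delta_deaths,
            "d_qalys_10y": res.econ_10y.delta_qalys,
        })
    if len(failures) > spec.max_failure_fraction * spec.n_draws:
        detail = "; ".join(failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{spec.n_draws} PSA draws failed (limit "
            f"{spec.max_failure_fraction:.0%}): {detail}"
        )
    return PSAResult(draws=pd.DataFrame(rows), n_failed=len(failures),
                     point_90d=point.econ_90d, point_10y=point.econ_10y)


def default_thresholds() -> np.ndarray:
    """£0-£50,000/QALY grid including the £20,000 and £30,000 NICE bounds."""
    return np.arange(0.0, 50_001.0, 1_000.0)


def ceac(result: PSAResult, thresholds=None, horizon: str = "90d") -> pd.DataFrame:
    """P(cost-effective) = fraction of draws with lambda*dQALY - dCost > 0."""
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if len(result.draws) < 2:
        raise ValueError("CEAC needs at least 2 draws")
    d_cost = result.draws[f"d_cost_{horizon}"].to_numpy()
    d_qaly = result.draws[f"d_qalys_{horizon}"].to_numpy()
    probs = [(lam * d_qaly - d_cost > 0).mean() for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds, "prob_cost_effective": probs})


# ---------------------------------------------------------------------------
# Deterministic scenario battery
# ---------------------------------------------------------------------------


def _scenario_central(inputs: AnalysisInputs) -> AnalysisInputs:
    return inputs


def _scenario_unadjusted(inputs: AnalysisInputs) -> AnalysisInputs:
    return replace(inputs, adjustments=replace(inputs.adjustments,
                                               adjust_mortality=False, adjust_los=False))


def _scenario_mortality_only(inputs: AnalysisInputs) -> AnalysisInputs:
    return replace(inputs, adjustments=replace(inputs.adjustments, adjust_los=False))


def _scenario_los_only(inputs: AnalysisInputs) -> AnalysisInputs:
    return replace(inputs, adjustments=replace(inputs.adjustments, adjust_mortality=False))


def _scenario_hasu_cost(inputs: AnalysisInputs) -> AnalysisInputs:
    return replace(inputs, costs=inputs.costs.scaled({"HASU": 1.25}))


def _scenario_nhs_only(inputs: AnalysisInputs) -> AnalysisInputs:
    return replace(inputs, costs=replace(inputs.costs, perspective="NHS-only"))


def _scenario_inpatients_home(inputs: AnalysisInputs) -> AnalysisInputs:
    return replace(inputs, inpatient_rule="home")


def _scale_ward_mean(fits: PeriodFits, ward: str, delta_days: float | None = None,
                     factor: float | None = None) -> PeriodFits:
    if ward not in fits.exit_fits:
        return fits
    fit = fits.exit_fits[ward]
    if factor is not None:
        new = fit.with_scale(fit.scale * factor)
    else:
        mean = fit.mean()
        if mean + delta_days <= 0:
            raise ValueError(f"{ward}: mean stay would become non-positive")
        new = fit.with_scale(fit.scale * (mean + delta_days) / mean)
    return replace(fits, exit_fits={**fits.exit_fits, ward: new})


def _scenario_reduced_hasu_los(inputs: AnalysisInputs) -> AnalysisInputs:
    # assumption: one further day off the mean HASU stay
    return replace(inputs, fits_after=_scale_ward_mean(inputs.fits_after, "HASU", delta_days=-1.0))


def _scenario_icu_los(inputs: AnalysisInputs) -> AnalysisInputs:
    # assumption: lift the central ICU stay trimming (mean +50% both arms)
    return replace(
        inputs,
        fits_before=_scale_ward_mean(inputs.fits_before, "ICU", factor=1.5),
        fits_after=_scale_ward_mean(inputs.fits_after, "ICU", factor=1.5),
    )


def _scenario_neurosurgery(inputs: AnalysisInputs) -> AnalysisInputs:
    # assumption: equalize neurosurgery rates at the 'after' level
    ev = inputs.costs.one_off.get("neurosurgery")
    if ev is None:
        return inputs
    prob = dict(ev.prob)
    prob["before"] = prob.get("after", 0.0)
    costs = replace(inputs.costs, one_off={**inputs.costs.one_off,
                                           "neurosurgery": replace(ev, prob=prob)})
    return replace(inputs, costs=costs)


SCENARIOS: dict[str, tuple] = {
    "central": (_scenario_central, {}),
    "north_london_slsr_only": (_scenario_central, {"use_alt_after": True}),
    "unadjusted": (_scenario_unadjusted, {}),
    "mortality_adjustment_only": (_scenario_mortality_only, {}),
    "los_adjustment_only": (_scenario_los_only, {}),
    "stroke_mimics": (_scenario_central, {"mimic_fraction": 0.10}),
    "reduced_hasu_los": (_scenario_reduced_hasu_los, {}),
    "hasu_cost_plus_25pct": (_scenario_hasu_cost, {}),
    "unadjusted_icu_los": (_scenario_icu_los, {}),
    "adjusted_neurosurgery_rates": (_scenario_neurosurgery, {}),
    "nhs_costs_only": (_scenario_nhs_only, {}),
    "inpatients_home_at_90d": (_scenario_inpatients_home, {}),
}

# assumption: a stroke mimic incurs a one-day admission plus imaging and
# accrues near-full health utility, with negligible attributable mortality
MIMIC_COST_PER_PATIENT = 1200.0
MIMIC_UTILITY = 0.80


def _blend_mimics(result, fraction: float):
    """Replace a fraction of the 'after' arm with stroke-mimic accruals."""
    from .econ import ArmResult

    def blend(arm: ArmResult) -> ArmResult:
        n_mimic = fraction * arm.cohort_size
        years = arm.horizon_days / 365.25
        return ArmResult(
            period=arm.period,
            horizon_days=arm.horizon_days,
            cohort_size=arm.cohort_size,
            total_cost=(1 - fraction) * arm.total_cost + n_mimic * MIMIC_COST_PER_PATIENT,
            total_qalys=(1 - fraction) * arm.total_qalys + n_mimic * MIMIC_UTILITY * years,
            deaths=(1 - fraction) * arm.deaths,
        )

    from .pipeline import AnalysisResult

    after90, after10 = blend(result.after.arm_90d), blend(result.after.arm_10y)
    after = replace(result.after, arm_90d=after90, arm_10y=after10)
    return AnalysisResult(before=result.before, after=after,
                          econ_90d=compare(result.before.arm_90d, after90),
                          econ_10y=compare(result.before.arm_10y, after10))


def run_scenarios(inputs: AnalysisInputs, names: list[str] | None = None) -> pd.DataFrame:
    """One deterministic result row per scenario per horizon.

    Columns follow the published result-table order: incremental cost,
    deaths, cost per death averted, QALYs, cost per QALY, dominance.
    """
    names = list(SCENARIOS) if names is None else names
    unknown = [n for n in names if n not in SCENARIOS]
    if unknown:
        raise ValueError(f"unknown scenario(s) {unknown}; available: {sorted(SCENARIOS)}")
    rows = []
    for name in names:
        transform, opts = SCENARIOS[name]
        use_alt = opts.get("use_alt_after", False)
        if use_alt and inputs.fits_after_alt is None:
            raise ValueError(f"scenario {name!r} needs the restricted 'after' register fits")
        result = run_analysis(transform(inputs), use_alt_after=use_alt)
        if "mimic_fraction" in opts:
            result = _blend_mimics(result, opts["mimic_fraction"])
        for horizon, econ in (("90d", result.econ_90d), ("10y", result.econ_10y)):
            rows.append({
                "scenario": name,
                "horizon": horizon,
                "delta_cost": econ.delta_cost,
                "delta_deaths": econ.delta_deaths,
                "icer_per_death_averted": econ.icer_per_death_averted,
                "delta_qalys": econ.delta_qalys,
                "icer_per_qaly": econ.icer_per_qaly,
                "dominance": econ.dominance,
            })
    return pd.DataFrame(rows)
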