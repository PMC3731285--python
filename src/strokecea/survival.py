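"""Survival estimation for the register data.

Three estimators feed the cohort models:

* Kaplan-Meier product-limit curves with plain Greenwood 95% intervals
  (non-parametric check on the fitted models);
* Weibull proportional-hazards maximum-likelihood fits, one per period and
  per transition, parameterized S(t) = exp(-(t/scale)^shape * exp(x'beta)).
  Separate per-period fits allow different shape parameters;
* age-adjusted Cox proportional-hazards models (semi-parametric contrast of
  the two periods).

Fitted Weibull hazards convert to per-day transition probabilities via
p(day) = 1 - S(day+1)/S(day), the bridge into the day-cycle Markov model.

Conventions: survival times of zero (death on the admission day) are imputed
as 0.5 days before parametric fitting, matching the daily time grid. The
Weibull covariance is reported on the (log shape, log scale, beta...) scale
so sensitivity analysis can sample it with a multivariate normal while
keeping parameters positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "KMCurve",
    "SurvivalFit",
    "CoxFit",
    "km_estimate",
    "fit_weibull",
    "fit_cox",
    "daily_transition_prob",
    "NonConvergenceError",
]


class NonConvergenceError(RuntimeError):
    """Parametric fit failed to converge (e.g. degenerate event times)."""


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood 95% intervals.

    At tied times, events are handled before censorings (the standard
    risk-set convention). All-censored input yields an empty event list and
    S(t) = 1 everywhere.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival time")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    table = table[table["observed"] > 0]
    event_times = table.index.to_numpy(dtype=float)
    n_risk = table["at_risk"].to_numpy(dtype=float)
    n_event = table["observed"].to_numpy(dtype=float)

    surv = np.array([kmf.survival_function_at_times(t).iloc[0] for t in event_times])
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), np.inf)
    var = surv**2 * np.cumsum(terms)
    se = np.sqrt(np.where(np.isfinite(var), var, 0.0))
    ci_low = np.clip(surv - 1.96 * se, 0.0, 1.0)
    ci_high = np.clip(surv + 1.96 * se, 0.0, 1.0)
    return KMCurve(event_times, surv, ci_low, ci_high, n_risk, n_event)


@dataclass(frozen=True)
class SurvivalFit:
    """Weibull (or exponential) PH fit: S(t|x) = exp(-(t/scale)^shape e^{x'b}).

    params/covariance are on the (log shape, log scale, *beta) scale;
    param_names records the order. period labels which register the fit
    came from; transition labels what hazard it models (e.g. 'death',
    'exit:ASU').
    """

    family: str  # weibull | exponential
    shape: float
    scale: float
    coefficients: dict[str, float]
    params: np.ndarray
    covariance: np.ndarray
    param_names: tuple[str, ...]
    log_likelihood: float
    n: int
    n_events: int
    period: str = ""
    transition: str = ""

    def survival_function(self, t, covariates: dict[str, float] | None = None):
        t = np.asarray(t, dtype=float)
        lp = 0.0
        if covariates:
            lp = sum(self.coefficients[k] * v for k, v in covariates.items())
        return np.exp(-((np.maximum(t, 0.0) / self.scale) ** self.shape) * np.exp(lp))

    def mean(self) -> float:
        """Mean survival time scale*Gamma(1+1/shape) (baseline covariates)."""
        from scipy.special import gamma

        return self.scale * gamma(1.0 + 1.0 / self.shape)

    def with_scale(self, scale: float) -> "SurvivalFit":
        new_params = self.params.copy()
        new_params[1] = np.log(scale)
        return replace(self, scale=scale, params=new_params)


def _weibull_neg_loglik(theta, t, d, X, fix_shape):
    if fix_shape is None:
        log_k, log_lam = theta[0], theta[1]
        beta = theta[2:]
    else:
        log_k, log_lam = np.log(fix_shape), theta[0]
        beta = theta[1:]
    k, lam = np.exp(log_k), np.exp(log_lam)
    lp = X @ beta if X is not None else 0.0
    z = t / lam
    log_h = log_k - log_lam + (k - 1.0) * np.log(z) + lp
    cum_h = z**k * np.exp(lp)
    return -(np.sum(d * log_h) - np.sum(cum_h))


def fit_weibull(
    times,
    events,
    covariates: pd.DataFrame | None = None,
    fix_shape: float | None = None,
    period: str = "",
    transition: str = "",
) -> SurvivalFit:
    """Maximum-likelihood Weibull PH fit with observed-information SEs.

    Zero survival times are imputed as 0.5 days. Fixing ``fix_shape=1``
    reduces to the exponential model (closed form: scale = total time at
    risk / events when there are no covariates). Degenerate inputs (no
    events, or all events at one instant) raise rather than returning a
    silent default.
    """
    t = np.asarray(times, dtype=float).copy()
    d = np.asarray(events, dtype=float)
    if t.shape != d.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    t[t == 0.0] = 0.5
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("cannot fit: no events observed")
    if fix_shape is None and n_events < 2:
        raise ValueError("cannot fit: need >= 2 events for a free shape")

    X = None
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        X = covariates.to_numpy(dtype=float)
        cov_names = tuple(covariates.columns.astype(str))

    event_t = t[d > 0]
    if fix_shape is None and np.ptp(event_t) == 0 and np.all(t == event_t[0]):
        raise NonConvergenceError("all events at a single instant; shape unbounded")

    # moment-flavoured start: exponential scale, shape 1
    scale0 = max(t.sum() / n_events, 1e-6)
    n_beta = 0 if X is None else X.shape[1]
    x0 = np.concatenate(([0.0] if fix_shape is None else [], [np.log(scale0)], np.zeros(n_beta)))
    args = (t, d, X, fix_shape)
    res = optimize.minimize(_weibull_neg_loglik, x0, args=args, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
    res = optimize.minimize(_weibull_neg_loglik, res.x, args=args, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 1000})
    if not np.all(np.isfinite(res.x)) or abs(res.x).max() > 30:
        raise NonConvergenceError(f"Weibull fit diverged: parameters {res.x}")

    if fix_shape is None:
        log_k, log_lam, beta = res.x[0], res.x[1], res.x[2:]
    else:
        log_k, log_lam, beta = np.log(fix_shape), res.x[0], res.x[1:]
    shape, scale = float(np.exp(log_k)), float(np.exp(log_lam))

    full = np.concatenate(([log_k], [log_lam], beta))
    names = ("log_shape", "log_scale") + cov_names
    with np.errstate(all="ignore"):
        try:
            if fix_shape is None:
                hess = approx_hess1(full, lambda th: _weibull_neg_loglik(th, t, d, X, None))
                cov = np.linalg.inv(hess)
            else:
                hess_red = approx_hess1(res.x, lambda th: _weibull_neg_loglik(th, t, d, X, fix_shape))
                cov_red = np.linalg.inv(hess_red)
                cov = np.zeros((len(full), len(full)))  # fixed shape: zero variance row/col
                idx = np.arange(1, len(full))
                cov[np.ix_(idx, idx)] = cov_red
        except np.linalg.LinAlgError:
            raise NonConvergenceError("observed information not invertible")
    if not np.all(np.isfinite(np.diag(cov))) or np.any(np.diag(cov) < -1e-8):
        raise NonConvergenceError("observed information not positive definite")
    cov = (cov + cov.T) / 2.0

    return SurvivalFit(
        family="exponential" if fix_shape == 1 else "weibull",
        shape=shape,
        scale=scale,
        coefficients=dict(zip(cov_names, (float(b) for b in beta))),
        params=full,
        covariance=cov,
        param_names=names,
        log_likelihood=-float(res.fun),
        n=int(t.size),
        n_events=n_events,
        period=period,
        transition=transition,
    )


@dataclass(frozen=True)
class CoxFit:
    """Cox PH fit (Efron ties): coefficients, hazard ratios and Wald CIs."""

    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    se: dict[str, float]
    log_likelihood: float
    ties: str
    n: int
    n_events: int
    flags: tuple[str, ...] = ()


def fit_cox(times, events, covariates: pd.DataFrame) -> CoxFit:
    """Age-adjusted (or general) Cox PH fit via lifelines (Efron ties).

    Constant covariates are rejected up front (non-identifiable); lifelines
    convergence warnings (e.g. possible perfect separation) are captured and
    surfaced on ``flags`` rather than silently discarded.
    """
    covariates = pd.DataFrame(covariates)
    if covariates.shape[1] < 1:
        raise ValueError("fit_cox requires at least one covariate")
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant: not identifiable")
    d = np.asarray(events, dtype=bool)
    if d.sum() < 2:
        raise ValueError("cannot fit: need >= 2 events")

    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = d.astype(int)
    cph = CoxPHFitter()
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        for w in caught:
            if "convergence" in str(w.message).lower() or "separation" in str(w.message).lower():
                flags.append(str(w.message))

    beta = cph.params_
    se = cph.standard_errors_
    return CoxFit(
        coefficients={k: float(v) for k, v in beta.items()},
        hazard_ratios={k: float(np.exp(v)) for k, v in beta.items()},
        ci_low={k: float(np.exp(beta[k] - 1.96 * se[k])) for k in beta.index},
        ci_high={k: float(np.exp(beta[k] + 1.96 * se[k])) for k in beta.index},
        se={k: float(v) for k, v in se.items()},
        log_likelihood=float(cph.log_likelihood_),
        ties="efron",
        n=int(df.shape[0]),
        n_events=int(d.sum()),
        flags=tuple(flags),
    )


def daily_transition_prob(fit: SurvivalFit, day: int) -> float:
    """Per-day transition probability p(day) = 1 - S(day+1)/S(day).

    Defined on the integer-day grid of the short-run model. If survival has
    already collapsed to zero by ``day``, the transition is certain and 1 is
    returned with a warning.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    s0 = float(fit.survival_function(float(day)))
    s1 = float(fit.survival_function(float(day + 1)))
    if s0 <= 0.0:
        warnings.warn(f"S({day}) = 0: state already absorbed; returning 1", RuntimeWarning)
        return 1.0
    return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))


def daily_transition_probs(fit: SurvivalFit, n_days: int) -> np.ndarray:
    """Vectorized p(0..n_days-1); same definition as daily_transition_prob."""
    days = np.arange(n_days + 1, dtype=float)
    s = fit.survival_function(days)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - s[1:] / s[:-1]
    p = np.where(s[:-1] <= 0.0, 1.0, p)
    return np.clip(p, 0.0, 1.0)
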