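# strokecea

Before/after comparative-effectiveness and cost-effectiveness modelling of
centralized acute stroke care, built for health economists and service
evaluators studying hospital-pathway reconfigurations.

In July 2010 London replaced thirty local acute stroke services with a
hub-and-spoke model: eight hyper-acute stroke units (HASUs) providing
continuous specialist care for the first 72 hours, feeding stroke units
(SUs) for ongoing inpatient care. Because a randomized trial of a city-wide
reconfiguration is impossible, the evaluation design is a before/after
contrast on patient-level register data, adjusted for national secular
trends in stroke mortality and length of stay. This package implements that
full analysis as a tested, reusable pipeline, with a synthetic-register
generator standing in for the (non-public) register data.

## What it computes

**Survival.** Kaplan-Meier curves with Greenwood intervals; age-adjusted Cox
proportional-hazards contrasts of the two periods; per-period Weibull
proportional-hazards fits, S(t) = exp(-(t/λ)^k), fitted separately per
period so the shape k can differ. Fitted hazards become per-day transition
probabilities via p(t) = 1 - S(t+1)/S(t).

**Two time-dependent Markov cohort models** over a hypothetical cohort of
6,438 strokes per year:

* *admission → 90 days*, one-day cycles, states = ward types (HASU, ASU,
  SU, stroke rehabilitation, medical, surgical, ICU) and discharge
  locations (home, home with early supported discharge, nursing home),
  plus absorbing death;
* *90 days → 10 years*, 90-day cycles, states = three home states banded by
  Barthel index (independent 15-20, moderate 10-14, dependent 0-9),
  institutional care, and death; costs and QALYs discounted at 3.5%/year.

**National-trend adjustments** to the 'before' arm: 30-day cumulative
mortality reduced by 2.4 percentage points (hazard scaling over days 0-29,
solved by bisection) and mean stroke-unit stay reduced by 5.0 days (Weibull
scale rescaling).

**Economics.** NHS + Personal Social Services costing in 2010/11 UK£
(per-bed-day, per-cycle, and one-off imaging/intervention costs as expected
values), Barthel-derived utilities, QALY accrual, incremental
cost-effectiveness ratios, and the dominance rule (dominant = cheaper with
fewer deaths or more QALYs).

**Uncertainty.** Probabilistic sensitivity analysis (beta event
probabilities, gamma unit costs, multivariate-normal survival parameters on
the log scale, Dirichlet transition mixtures), percentile confidence
intervals, cost-effectiveness acceptability curves over £0-£50,000/QALY,
and a deterministic scenario battery.

The synthetic-register generator is calibrated to the published cohort
marginals (age, sex, stroke type, thrombolysis rates, admission Barthel,
first-ward mix) and to the published 90-day Kaplan-Meier survival anchors
of 81.5% ('before') and 88.7% ('after'). Unit costs, utilities per state
and long-run transition probabilities are clearly-labelled assumption
defaults, since the study's supplementary tables are not reproduced here;
see `docs/methods.md`.

## Worked example

```python
from strokecea import (AnalysisInputs, default_config, fit_period,
                       generate_cohort, period_hazard_ratio, run_analysis)

before = generate_cohort(default_config("before", seed=7))   # n = 307
after = generate_cohort(default_config("after", seed=8))     # n = 3,156

cox = period_hazard_ratio(before, after)
print(f"age-adjusted hazard ratio (after vs before): "
      f"{cox.hazard_ratios['period_after']:.2f} "
      f"(95% CI {cox.ci_low['period_after']:.2f}-{cox.ci_high['period_after']:.2f})")

inputs = AnalysisInputs(fits_before=fit_period(before), fits_after=fit_period(after))
res = run_analysis(inputs)
print(f"model survival at 90 days: before (adjusted) {res.before.survival_90d():.1%}, "
      f"after {res.after.survival_90d():.1%}")
e = res.econ_90d
print(f"90 days:  delta cost = {e.delta_cost:+,.0f} GBP "
      f"({e.per_patient_delta_cost():+,.0f}/patient), "
      f"delta deaths = {e.delta_deaths:+.0f}, delta QALYs = {e.delta_qalys:+.1f} -> {e.dominance}")
e = res.econ_10y
print(f"10 years: delta cost = {e.delta_cost:+,.0f} GBP, "
      f"delta QALYs = {e.delta_qalys:+,.0f} -> {e.dominance}")
```

prints:

```
age-adjusted hazard ratio (after vs before): 0.61 (95% CI 0.50-0.74)
model survival at 90 days: before (adjusted) 84.4%, after 88.8%
90 days:  delta cost = -2,795,455 GBP (-434/patient), delta deaths = -280, delta QALYs = +217.1 -> dominant
10 years: delta cost = -71,411,600 GBP, delta QALYs = +4,781 -> dominant
```

Reading: with registers drawn at the two calibrated survival anchors, the
centralized model shows a mortality hazard roughly 40% lower after
age adjustment; propagated through the cohort models it saves money while
averting deaths and gaining QALYs at both horizons — i.e. it *dominates*
the previous configuration, so no cost-effectiveness ratio is reported.
Cost magnitudes depend on the assumption unit costs and will differ from
evaluations using confidential register and tariff data.

There is also a CLI:

```bash
strokecea --config config.yaml simulate   # write synthetic registers
strokecea --config config.yaml run        # deterministic 90-day + 10-year reports
strokecea --config config.yaml psa --plot # PSA draws, CEACs, figures
strokecea --config config.yaml scenarios  # deterministic sensitivity battery
```

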