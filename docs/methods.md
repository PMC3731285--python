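# Methods

This note documents the models, the calibration of the synthetic register
generator, the numerical choices, and the limitations of what the test
suite can and cannot establish.

## Study design being modelled

A city-wide reconfiguration of acute stroke care is evaluated as a
before/after contrast: registers of stroke admissions from the year before
the change and the year after are compared on survival, length of stay,
costs, and quality-adjusted survival, with the 'before' arm adjusted for
the mortality and length-of-stay improvements that occurred nationally over
the same interval (so that the contrast isolates the reconfiguration from
secular trend). Outcomes are propagated through two Markov cohort models
over a hypothetical annual cohort of 6,438 strokes.

## Synthetic register generator

Real stroke registers are not publicly available, so the generator emulates
their structure: one row per admission with period label, demographics,
stroke type, thrombolysis flag, dated ward episodes, discharge destination,
death or censoring day, and Barthel scores at admission and 90 days.

Generative scheme, per patient:

* demographics and stroke type are independent draws matching the published
  cohort marginals (age ~ N(71, 15.2) 'before' and N(72.8, 14.9) 'after',
  clipped to [18, 105]; 51% male; 85%/88% ischemic; thrombolysis 5%/13%,
  drawn only among ischemic strokes so the marginal rate matches);
* one latent all-cause death time is drawn from a period-specific Weibull;
* the first ward is drawn from the period's observed first-ward mix; each
  ward episode draws a latent Weibull sojourn, and the earlier of death and
  ward exit ends the episode (ties break death-first). Live exits move to
  another ward or a discharge destination by a per-ward mixture; discharged
  patients stay in the community until death or censoring (default 365
  days of follow-up, so 90-day outcomes are fully observed);
* times are recorded on an integer-day grid, day 0 = admission, with
  death day = floor of the latent time.

**Survival calibration.** The only published survival anchors are the
90-day Kaplan-Meier rates, 81.5% 'before' and 88.7% 'after'. For a Weibull
with shape k, the anchor pins the scale exactly:
λ = 90 / (-ln S(90))^(1/k) (`calibrate_death_scale`). The shape k = 0.6 is
shared by both periods and chosen once to represent the steeply declining
post-stroke death hazard; sharing the shape makes the implied cumulative-
hazard ratio at 90 days ln(0.887)/ln(0.815) ≈ 0.59 independent of k —
inside the published age-adjusted Cox interval (0.41-0.72) and close to its
0.54 point estimate. This consistency is verified over 50 seeded replicates
in the acceptance suite.

**Ward sojourns and destinations** are Weibull/multinomial stand-ins
anchored to the published first-ward median stays (e.g. ASU median 4 days
'before', HASU median 3 days 'after') with heavy-tailed shapes (k = 0.6-0.8,
realistic for length-of-stay), and destination mixtures chosen so that
roughly 60%/5% of 'before' patients and 70%/1% of 'after' patients are at
home / in a nursing home by day 90, as reported. Barthel at 90 days is
admission Barthel plus a normal improvement (mean +3 'before', +4 'after'),
clipped to [0, 20]; the improvement parameters are free assumptions, since
only admission-time Barthel means are published.

What the generator does **not** emulate: record linkage and consent
artifacts, missing data, within-90-day stroke recurrence, and any joint
dependence of age × severity × pathway (they are independent by default; a
passing test suite therefore says nothing about confounding structures in
real registers).

## Survival estimation

* Kaplan-Meier via the product-limit estimator with plain Greenwood
  variance; at tied times events precede censorings.
* Weibull proportional hazards, S(t|x) = exp(-(t/λ)^k e^{x'β}), fitted by
  maximum likelihood (Nelder-Mead polish + BFGS); standard errors from the
  numerically-differentiated observed information. The covariance is kept
  on the (log k, log λ, β) scale so the PSA can sample it with a
  multivariate normal while keeping parameters positive. Fixing k = 1
  reduces to the exponential model and matches its closed form to 1e-9.
  Covariate-free fits agree with an independent library implementation
  and with a grid-search likelihood maximizer in the tests.
* Cox proportional hazards via partial likelihood with **Efron** tie
  handling (the library standard; on tie-free data it coincides with
  Breslow, which is what the brute-force oracle test uses). Constant
  covariates are rejected; convergence/separation warnings are surfaced as
  flags, never clipped silently.
* Survival times of 0 days (death on the admission day) are imputed as 0.5
  days before parametric fitting — the natural half-day on an integer-day
  grid.
* Censoring follows the register convention: date of death, else date of
  last follow-up.
* Sparse wards degrade gracefully: fewer than 5 live exits → exponential
  sojourn; zero live exits → the MLE limit of a zero exit hazard (the ward
  empties only through death).

## Short-run cohort model (admission → 90 days)

Daily transition matrices over ward + discharge states. The period-wide
death hazard (a function of days since admission) applies to every alive
state, which makes the model's marginal survival reproduce the fitted
survival curve exactly; ward-exit hazards are fitted on time-in-ward and
applied on the days-since-admission axis — exact for first wards (entered
at day 0), an approximation for downstream wards, inherent to a cohort
model without tunnel states. Competing risks within a day are composed on
the rate scale: r = -ln(1-p) per marginal risk, total exit 1 - exp(-Σr),
allocated proportionally to rates (order-independent). No half-cycle
correction: with one-day cycles the correction is far below every other
uncertainty.

The initial distribution is the register's first-admitted-ward mix. The
cohort trace is validated cycle-by-cycle (conservation to 1e-6, death
monotonicity) and checked against an independent count-based
microsimulation with 100,000 walkers.

**Mortality trend adjustment** (default 2.4 percentage points at 30 days):
all into-death entries over days 0-29 are scaled by one factor found by
bisection so cumulative death occupancy at cycle 30 falls by exactly the
requested amount; freed mass returns to each source state's diagonal;
hazards from day 30 are untouched. This preserves the hazard shape. An
alternative mode concentrates the whole reduction in the day-29 transition
(a literal "subtract deaths at 30 days"); both are implemented, scaling is
the default.

**Length-of-stay trend adjustment** (default 5.0 days): the 'before'
acute-stroke-unit exit Weibull scale is multiplied by
(mean - 5.0)/mean, using mean = λΓ(1 + 1/k); the schedule is rebuilt.
The adjustment targets the ASU because it is the 'before' period's
stroke-unit ward; the rehabilitation ward is untouched.

Both adjustments apply to the 'before' arm only.

## Long-run model (90 days → 10 years)

Forty 90-day cycles over five states: three home states banded by Barthel
(independent 15-20, moderate 10-14, dependent 0-9), institutional care,
death. Day-90 survivors are seeded from the short-run trace: home and ESD
discharges split across home bands by the register's 90-day Barthel band
mixture (or a normal-approximation default when fewer than 10 observations
exist); nursing-home discharges enter institutional care; patients still in
hospital go to institutional care by default, or home under the scenario
flag.

The default transition matrices are a **calibrated stand-in, not published
values**: per-90-day death probability rising with dependence (1.5% home
independent → 8% institutional, i.e. roughly 6-28% annualized), plus a mild
drift toward dependence. They ship as an editable config structure
(`DEFAULT_LONG_RUN_MOVES`).

Discounting: 3.5% per year, factor (1.035)^(-day/365.25), applied to both
costs and QALYs at the **mid-cycle day** — with 90-day cycles timing
matters; mid-cycle halves the first-order error of either end-point
convention. The 90-day horizon is undiscounted.

## Economics

Perspective: NHS + Personal Social Services, 2010/11 UK£; an NHS-only
perspective zeroes the items flagged PSS (nursing-home / institutional
care). Ward states carry per-bed-day costs, long-run states per-cycle
costs, and one-off events (ambulance, CT, MRI, CT-angiography,
echocardiogram, carotid stenting, neurosurgery, thrombolysis) are costed as
expected values at admission using the published per-period event rates.
All unit-cost magnitudes are assumptions (the study's unit-cost table is
not reproduced); they are deliberately plain data, overridable in config,
and every totals-level result is linear in them.

Utilities come from the Barthel index through a configurable map whose
default is the affine calibration u = 0.05·BI - 0.235 clipped to
[-0.235, 1]. This passes exactly through the two published (mean Barthel,
mean utility) pairs, (9.3, 0.23) and (10.7, 0.30); it is a calibration
stand-in for the published mapping algorithm, whose coefficients are not
printed. Short-run inpatient states carry the period's admission-Barthel
utility, home states the improved 90-day utility, long-run states their
band-midpoint utility.

Dominance follows the published footnote rule: *dominant* iff costs are
lower and either deaths are lower or QALYs are higher; *dominated* is the
mirror; ICERs are reported only in trade-off quadrants.

## Sensitivity analysis

Deterministic scenarios (each a named config override): unadjusted /
mortality-only / LOS-only trend adjustment, restricted 'after' data
sources, stroke-mimic dilution (10% of the 'after' cohort as low-cost
mimics — magnitude assumed), HASU mean stay -1 day, HASU unit cost +25%,
ICU stay untrimmed (+50% mean), neurosurgery rates equalized, NHS-only
costing, and in-hospital-at-90-days patients seeded home.

PSA distribution families follow standard health-economics practice (the
study's parameter table is not published): beta for event probabilities
(effective sample size = the period's register size), gamma for unit costs
(CV 20%), multivariate normal on the log scale for survival parameters
using each fit's observed-information covariance, Dirichlet for destination
mixtures (observed counts + 1/2) and long-run rows (concentration 200).
Transition parameters are sampled independently across blocks; joint
sampling within a fit uses its covariance. Each draw rebuilds both arms'
schedules, re-solves the mortality-adjustment bisection, runs both
horizons, and records the increments; per-draw failures are excluded and
counted, and more than 1% failing aborts the run. The library default is
10,000 draws; `scripts/acceptance.py` uses 1,000 (its Monte-Carlo error on
the reported means is well under the parameter uncertainty it propagates),
and the test suite smaller sizes still.

## Numerical choices and degenerate inputs

* Weibull parameterization is S(t) = exp(-(t/λ)^k) everywhere λ appears.
* Bisection for the mortality adjustment: 80 iterations on [0, 1] (factor
  resolved to machine precision); infeasible targets (requested reduction
  exceeding attainable deaths) raise before any propagation.
* Row-stochasticity, conservation and death-monotonicity are asserted at
  build and propagation time with 1e-9/1e-6 tolerances.
* Degenerate survival inputs raise explicit errors: no events, all events
  at one instant (shape unbounded), non-invertible information.
* Certain (p = 1) daily risks absorb the whole row, split evenly among the
  certain risks.

## Problem sizes

Registers default to the study sample sizes (307 'before', 3,156 'after',
319 restricted 'after'); statistical tests use up to 10,000 patients where
convergence is asserted, and the microsimulation oracle uses 100,000
walkers. These sizes were chosen so every check is decisively powered while
the whole suite runs in well under a minute of compute per module.

## Known limitations

* Cost and long-run-transition magnitudes are assumptions; only the signs,
  orderings, and arithmetic identities of economic outputs are meaningful
  against external data, not their absolute values.
* Ward-exit hazards are applied on the days-since-admission axis for
  downstream wards (see above).
* The Barthel→utility map is a two-point affine calibration; ceiling/floor
  effects of the Barthel index are inherited, not corrected.
* The generator's independence assumptions mean age adjustment in the Cox
  model is exercised structurally but cannot exhibit real confounding.
* No US$ conversion is provided.
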