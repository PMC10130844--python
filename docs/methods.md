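# Methods

## The question and the design

`heatlag` estimates the short-term association between daily minimum
temperature (Tmin) and mental-health-related emergency-department visits
and unscheduled hospitalizations in young people (ages 6–25), using a
time-stratified case-crossover design with a distributed-lag non-linear
model (DLNM).

Each encounter contributes one matched set: the admission day is the
case day, and the referents are every other day in the same calendar
month and year falling on the same day of week (3 or 4 of them — a
weekday occurs 4 or 5 times in any month). Because each person serves as
their own control, all time-invariant personal characteristics cancel;
because referents share year, month and weekday with the case day,
long-term trends, seasonality and weekday patterns are controlled by
matching rather than by modelling.

Tmin is the exposure because nighttime heat and the sleep disruption it
causes are a leading hypothesized pathway from heat to acute mental
health episodes. The analysis is restricted to the warm season
(June–August) over a multi-year study window (2005–2011 by default).

## The model

Within each matched set the probability that the event fell on day *d*
rather than on one of its referents follows the conditional-logistic
form

    P(case = d | set S) = exp(x_d'β) / Σ_{j∈S} exp(x_j'β),

where x_d is the cross-basis row for day *d*: a natural cubic spline in
Tmin (default 3 df: interior knots at the 33.3rd/66.7th percentiles of
the analysis sample's warm-season Tmin, boundary knots at the observed
min/max) crossed with an unconstrained integer-lag structure over lags
0–5 (one spline-coefficient block per lag day). With df = 3 and 6 lags
the design has 18 columns, ordered lag-major. The spline uses the
truncated-power natural-spline construction (linear beyond the boundary
knots, C² everywhere); any invertible column transform spans the same
space and gives identical fitted curves, which the tests verify.

The likelihood is maximized directly (the matched sets have at most 4
referents, so the exact denominator is cheap) by Newton–Raphson with
analytic gradient and Hessian, step-halving on any likelihood decrease,
starting from β = 0. Convergence: max |score| < 1e-8 or relative
log-likelihood change < 1e-12, at most 50 iterations. The covariance is
the inverse observed information at the optimum. Strata whose rows are
all identical carry no information; they are counted and excluded from
the information. Separation (a column that perfectly ranks cases above
or below all their referents) is detected and reported as an error,
never shrunk away. All tolerances are package choices.

### Cumulative curve, MRT, and odds ratios

The cumulative lag-0–5 log odds ratio for temperature *t* versus a
reference *r* places the same spline difference b(t) − b(r) in every lag
block: cum log-OR(t) = c(t)'β̂ with SE sqrt(c(t)'Σ̂c(t)). The
minimum-risk temperature (MRT) is the grid temperature (0.1 °F
resolution, restricted to the observed warm-season range, ties broken
toward the colder end) minimizing this curve; the curve is then
re-referenced at the MRT, which shifts it by a constant and does not
move the minimizer. The headline estimate is the cumulative OR at the
warm-season 95th-percentile Tmin versus the MRT, with Wald confidence
intervals on the log scale. Uncertainty in the MRT's location is **not**
propagated into the CI — the convention in this literature, and a known
caveat: near the null the curve minimum sits below the value at the true
vertex, which biases the OR upward slightly and makes nominal coverage
approximate (quantified below).

### Subgroups and heterogeneity

Subgroup analyses (sex, race/ethnicity, payment source, diagnostic
subcategory, suicide flag) refit the conditional-logistic model on the
subset of strata, reusing the age group's knots so all subgroup curves
share one basis. Subgroups below the minimum size (500 encounters by
default) are reported as skipped. Each subgroup estimates its own MRT by
default (the reference may instead be shared via
`RunConfig.mrt_reference = "shared"`). Cochran's Q with fixed-effect
weights (w = 1/SE²) summarizes heterogeneity across each stratification
variable's subgroup log-ORs. Note that with subgroup-specific MRT
references the subgroup estimates share correlated reference noise and Q
is conservative (measured rejection ≈ 2% at α = 0.05); the calibration
experiment therefore uses the shared-reference mode, where Q's
independent-Wald assumptions hold and rejection is ≈ 5%.

### Sensitivity variants

* **RH-adjusted** — a single linear lag-0 relative-humidity covariate is
  appended to every design row (a spline in RH is deliberately out of
  scope; the covariate is a confounding check, not an exposure model).
  RH itself comes from the Magnus approximation
  e(T °C) ∝ exp(17.625·T/(243.04+T)), RH = 100·e(Td)/e(T), the formula
  family of the standard weather-conversion toolchain.
* **July–August restriction** — strata rebuilt from July and August
  cases only.

## Data handling choices

* All temperatures are °F internally; °F↔°C conversion is centralized.
* Station averaging is the per-day unweighted mean over stations
  reporting that day; a day with no reporting station is a hard gap.
  Any stratum whose lag-0–5 window touches a gap is dropped whole (not
  just the affected referent, to keep referent sets balanced within the
  month) and counted in the attrition log. The exposure series must
  extend at least 5 days before June 1 of each analysis year.
* Quantiles (the 95th-percentile contrast, knot placement) use linear
  interpolation between order statistics ("type 7"); the rule is
  recorded in the run manifest because ORs depend on it.
* Cohort filters run in a fixed order (calendar window → age →
  unscheduled → diagnosis) so attrition logs are comparable across runs.
* The diagnostic subcategory map is data, not algorithm: a default
  ICD-9 prefix map for the 17 pediatric mental-health categories is
  shipped, but it is approximate and fully overrideable via YAML.
  Categories whose canonical codes lie outside the default 290–299
  primary-case block (anxiety, ADHD, reaction, ...) only become case
  subcategories when the root range is widened in configuration.
* Records with unknown sex/race/payer stay in overall analyses and drop
  out only of the corresponding stratified analysis.

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes, so every
stage is testable without access to claims data.

* **Exposure** — daily Tmin is a centered annual sinusoid plus
  stationary AR(1) Gaussian noise (ρ = 0.7), calibrated so the
  June–August marginal moments match the study setting's mean 67.9 °F
  and SD 5.4 °F; values are clipped to a wide physical range. Only the
  warm season is calibrated; winter values exist to keep the series
  contiguous and are not meaningful climatology. Tmean is Tmin plus a
  fixed offset, and the dew point is set to realize a Gaussian RH target
  (mean 65%, SD 10), so RH is independent of the outcome by
  construction.
* **Encounters** — daily counts per age group are Poisson with
  log-rate = log(baseline) + day-of-week + month + year effects
  + Σ_l w_l·f(Tmin_{d−l}). Poisson event generation (rather than
  per-person Bernoulli) leaves the conditional likelihood of the matched
  sets unchanged and is simpler. Baselines default to the study
  setting's visit volumes (≈9.7 / 34.5 / 84.6 encounters per day for
  ages 6–11 / 12–17 / 18–25). Calendar effects are **on** by default and
  constant within (year, month, weekday) cells, so the matched design
  removes them exactly — tests demonstrate rather than assume the
  design's confounder control.
* **True response** — f(t) = a(t − v)² with vertex v = 69 °F and
  curvature a = 0.004 /°F², with geometrically decaying lag weights
  (0.35, 0.25, 0.18, 0.12, 0.07, 0.03; sum 1). The implied cumulative
  log-OR at the typical warm-season 95th percentile (≈76–77 °F) versus
  the vertex is ≈0.2–0.3 (OR ≈ 1.25–1.35), the magnitude scale of
  published heat/mental-health case-crossover estimates. The generating
  estimand Σ_l w_l·[f(t) − f(r)] is exposed for recovery tests, and a
  null setting (all w = 0) supports type-I-error studies.
* Demographics, payer and diagnosis category are drawn from visit-level
  mixtures matching the study setting's composition; what the generator
  does **not** emulate: spatial exposure variation, within-person
  repeat-visit correlation, seasonality in the diagnosis mix, and any
  real ICD-9 coding noise. Passing tests therefore show that the
  estimator works when its assumptions hold, not that those assumptions
  hold in claims data.

## Evaluation experiments and their problem sizes

The Monte-Carlo experiments (`heatlag.evaluation`) use compact two-year,
single-age-group studies: ~5,000 encounters per repetition for the null,
confounding, sensitivity and heterogeneity experiments (the scale at
which subgroup analyses operate), and ~15,500 (the young-adult visit
rate) for parameter recovery so Monte-Carlo noise does not swamp the
estimand. Repetition counts: 100 (null), 50 (recovery), 50 pairs
(confounding), 15 (RH), 20 (July–August), 200 (Cochran's Q).

Two measured properties deserve emphasis:

* **Spline approximation of the quadratic truth.** The generating
  response is a parabola, which no natural cubic spline can represent
  exactly (the natural constraint forces zero curvature at the boundary
  knots). At the 95th-percentile contrast this projects into a small
  systematic overshoot of the cumulative log-OR, measured at ≈ +0.03 in
  the large-sample limit of the default conditions (truth ≈ 0.23–0.38).
  The recovery experiment's mean error stays within ±0.05, but because
  the overshoot does not shrink with sample size, 95% CI coverage of the
  quadratic truth sits below nominal: 0.888 ± 0.020 measured over 250
  repetitions at the recovery scale, consistent with the bias-to-noise
  ratio (≈0.03/0.04) of these conditions. This is a property of spline
  approximation under a misspecified-by-construction truth, not of the
  fitting code: with an in-span (linear) generating response the
  estimator is unbiased to Monte-Carlo precision.
* **MRT referencing near the null.** Under a null effect the estimated
  curve minimum dips below zero by noise, so the OR at the 95th
  percentile versus the estimated MRT is positively biased; the measured
  fraction of null 95% CIs excluding OR = 1 is ≈ 6% rather than exactly
  5%.

## Known limitations

* Wald CIs do not account for MRT estimation or knot selection.
* The discrete conditional likelihood is exact for 1:m matched sets but
  no robust/sandwich variance is offered; with visit-level Poisson data
  this is the correct variance, while overdispersed real data would
  need more.
* Only the warm season and ICD-9-era coding are supported; referent
  schemes other than time-stratified are out of scope.
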