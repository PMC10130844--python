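# heatlag

Time-stratified case-crossover analysis of daily minimum temperature
(Tmin) and mental-health-related emergency-department visits and
hospitalizations in young people (ages 6–25), using a distributed-lag
non-linear model (DLNM).

The package is aimed at environmental-epidemiology analysts who want the
full chain as tested, reusable code: citywide exposure construction from
weather-station records, ICD-9 cohort filters and outcome taxonomy,
time-stratified referent selection, spline × integer-lag cross-basis,
conditional logistic regression, minimum-risk-temperature-referenced
cumulative odds ratios with subgroup heterogeneity, and the standard
sensitivity analyses — plus a synthetic-study generator so every stage
runs and is validated without access to restricted claims data.

## The model

Each encounter's admission day (case day) is matched to every other day
in the same month and year sharing its day of week (3–4 referents),
which removes trend, seasonality, weekday patterns and all
time-invariant personal factors by design. Within matched set *S*,

&nbsp;&nbsp;&nbsp;&nbsp;P(case = d | S) = exp(x_d′β) / Σ_{j∈S} exp(x_j′β),

where x_d is the DLNM cross-basis row: a natural cubic spline in Tmin
(3 df; interior knots at the 33.3/66.7 percentiles of the warm-season
analysis sample, boundary knots at the observed min/max) crossed with an
unconstrained integer-lag basis over lags 0–5 (18 columns). The
cumulative lag-0–5 log odds ratio for t versus reference r is
Σ_l [b(t) − b(r)]′β̂_l; the reference is the minimum-risk temperature
(MRT), the grid temperature (0.1 °F steps over the observed warm-season
range) at which the fitted cumulative curve is lowest. The headline
estimate is the cumulative OR at the warm-season 95th-percentile Tmin
versus the MRT, with Wald CIs on the log scale. Cochran's Q
(fixed-effect weights 1/SE²) tests heterogeneity across subgroup
estimates. See `docs/methods.md` for assumptions, numerical choices and
measured operating characteristics.

## Worked example

```python
import heatlag as hl

cfg = hl.SimulationConfig(years=(2005, 2006), baseline_daily={"18-25": 27.0})
study = hl.simulate_study(cfg, seed=42)           # exposure + ~5,500 visits
run = hl.RunConfig(years=(2005, 2006), subgroup_vars=("sex",))
bundle = hl.run_analysis(study.exposure, study.encounters, run)
print(bundle.results[["age_group", "variable", "level", "n", "mrt_f",
                      "t_elevated_f", "or", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
```

```
age_group variable   level    n  mrt_f  t_elevated_f    or  ci_low  ci_high
    18-25  overall overall 5515 67.634        77.166 1.337   1.178    1.517
    18-25      sex  female 2453 67.135        77.166 1.376   1.133    1.672
    18-25      sex    male 3062 68.233        77.166 1.303   1.104    1.538
```

Reading the output: in this simulated study the fitted cumulative
exposure–response for 18–25-year-olds is lowest at 67.6 °F (the MRT);
a day at the warm-season 95th percentile (77.2 °F) carries 1.34 times
the odds of a mental-health encounter, accumulated over lags 0–5
(95% CI 1.18–1.52). The generator's true cumulative log-OR for that
contrast is 0.267 (OR 1.31), inside the CI. `bundle.heterogeneity`
holds the Cochran's Q rows (here Q = 0.18, p = 0.67: no evidence the
sex-specific ORs differ), and `bundle.write(outdir)` exports
`results.csv`, per-group curve CSVs, `manifest.json` (knots, convergence
diagnostics, config hash) and the attrition log.

The same pipeline runs from the shell:

```sh
heatlag simulate --seed 42 --out data/
heatlag run --stations data/stations.csv --linelist data/encounters.csv --out out/
heatlag sensitivity --variant rh --stations data/stations.csv \
    --linelist data/encounters.csv --out out_rh/
heatlag report --results out/
```

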