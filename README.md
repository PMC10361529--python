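# odmobility

Fine-scale analysis of how within-city human mobility changed during the
early COVID-19 pandemic. The package provides a tested pipeline for
zip-code-level origin–destination (OD) trip data: baseline-relative
descriptive mobility metrics, two bespoke Bayesian count models fitted by
MAP with Laplace-approximate uncertainty under a censored Poisson
likelihood, a gravity-model alternative with BIC comparison, and a seeded
synthetic-data generator that emulates the statistical structure of
proprietary mobile-operator data (which cannot be redistributed).

It is aimed at infectious-disease epidemiologists and mobility modellers
who want to quantify *which* trips declined — by route distance, subscriber
income, age group and local case rates — rather than only how much overall
travel fell.

## The models

The observable is `Y_ijat`, the number of trips recorded between zip codes
`i` and `j` (either direction) in age group `a` and week `t`. Counts below
the operator's anonymity threshold (50) are withheld; such cells enter the
likelihood through the Poisson CDF, `log P(Y <= 49 | mu)`.

**Decline model** (first 9 weeks; the first 4 are the February baseline):

    Y_ijat ~ Poisson(p_ia * r_ija * q_ijat + p_ja * r_jia * q_jiat)
    log q_ijat = - exp(beta' X_ijt + beta_a) * sum_{k <= t} c_k

where `p_ia` is the subscriber count, `r_ija` a learned per-subscriber
baseline weekly rate, `c_k >= 0` city-wide weekly decrease increments
(zero during the baseline month), and `X_ijt` the covariates of the
origin zip and route: distance quartile (trip-weighted, Q2 reference),
proportion of higher-income subscribers (> $50k/yr), county case rate
relative to the city mean, and standardized median household income.
Because the observations pool directions, the default fit learns one
pooled rate per unordered pair and age (`rate_structure="pooled"`); a
directed parameterization is available.

**Summer model** (a stable multi-week block vs baseline):

    lambda_ija = n_weeks * exp(-(beta0 + beta' X_ij + beta_a)) * r_ija

with the baseline rates plugged in from the decline fit.

**Gravity alternative**: `r_ija = theta * p_ia^alpha * pbar_j^delta *
d(i,j)^gamma` replaces the free baseline rates; the two decline variants
are compared by BIC (`k ln n - 2 ln L`).

Inference is quasi-Newton MAP with analytic gradients and weakly
informative Normal priors; standard deviations come from the inverse
Hessian at the mode (Laplace approximation), computed by central
differences of the analytic gradient.

## Worked example

```python
from odmobility import (SimConfig, generate_city, simulate_decline_panel,
                        build_covariates, fit_decline, relative_mobility)

cfg = SimConfig(n_zips=12, seed=1)
city = generate_city(cfg)
panel, truth = simulate_decline_panel(city, cfg)

series = relative_mobility(panel, baseline_weeks={1, 2, 3, 4})
print(f"minimum weekly mobility: {series.min():.2f} x baseline (week {series.idxmin()})")

covs = build_covariates(panel, city, truth["cases"], quartile_period={1, 2, 3, 4})
fit = fit_decline(panel, covs, city)
summary = fit.summary()
print(summary[summary.param.str.startswith("beta:")].to_string(index=False))
print(f"BIC: {fit.bic:.1f}  converged: {fit.converged}")
```

prints

```
minimum weekly mobility: 0.49 x baseline (week 9)
                  param  estimate       sd    ci_low  ci_high
           beta:dist_q1  0.030953 0.012857  0.005754 0.056152
           beta:dist_q3  0.008989 0.012631 -0.015767 0.033745
           beta:dist_q4  0.523657 0.011007  0.502085 0.545230
beta:prop_higher_income  0.370301 0.041460  0.289040 0.451562
beta:relative_case_rate  0.098712 0.027632  0.044554 0.152870
 beta:median_income_std -0.001240 0.009196 -0.019264 0.016784
BIC: 15831.6  converged: True
```

Travel in this simulated city bottoms out at 49% of the February baseline
by week 9. The fitted effects recover the generative truth (longest-
distance routes decline fastest, `beta_dist_q4 = 0.52` vs a true 0.5;
higher-income zips decline faster, 0.37 vs 0.4; a small positive case-rate
effect; no effect of area-level median income): positive coefficients mean
a *faster* weekly decrease on those routes.

A command-line interface mirrors the library
(`odmobility simulate | describe | fit-decline | fit-summer | fit-gravity
| compare | run-all`); `run-all` executes the whole single-city pipeline
from a YAML config with a manifest for resumable, seeded runs.

## Layout

- `odmobility.io_prep` — containers (`ZipTable`, `TripPanel`,
  `CovariateSet`), CSV I/O, weekly aggregation, haversine distances,
  trip-weighted distance quartiles, covariate assembly.
- `odmobility.synthetic` — seeded generator for cities, decline panels and
  summer blocks, returning generative truth for recovery studies.
- `odmobility.descriptive` — baseline-relative series, income-ratio
  series, stratified series, city-level correlations.
- `odmobility.likelihood` — the censored Poisson kernel.
- `odmobility.decline`, `odmobility.summer`, `odmobility.gravity` — the
  three model fits and BIC comparison.
- `odmobility.pipeline`, `odmobility.cli` — orchestration and CLI.

See `docs/methods.md` for modelling assumptions, priors, numerical choices
and known limitations.
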