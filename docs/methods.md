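# Methods

## Setting

The package models weekly trip counts between pairs of zip codes within a
US city, as recorded by a mobile operator, over two windows of 2020: the
initial pandemic decline (nine weeks from early February, of which the
first four are the pre-pandemic baseline) and a stable summer block. The
operator data that motivated this design is proprietary; the package
therefore ships a generator that produces synthetic cities with the same
statistical structure, and every model is validated by parameter recovery
on that synthetic data.

Two features of the data shape everything else:

1. **Anonymity censoring.** Counts below 50 are withheld. A censored cell
   contributes `log P(Y <= 49 | mu)` to the likelihood, evaluated through
   the regularized upper incomplete gamma function with a log-sum-exp
   fallback where that underflows (stable for means beyond 1e7).
2. **Direction ambiguity.** A recorded trip from i to j may be an outward
   trip by a resident of i or a return trip by a resident of j, so the
   count between i and j pools both directions:
   `Y ~ Poisson(p_ia λ_ijat + p_ja λ_jiat)` with `p_ia` the subscriber
   count of zip i in age group a.

## Decline model

Rates factor into a baseline and a decline fraction,
`λ_ijat = r_ija q_ijat`, with

    log q_ijat = - exp(beta' X_ijt + beta_a) * Σ_{k<=t} c_k .

The increments `c_k >= 0` (parameterized on the log scale) are city-wide
weekly decreases; the exponential factor modulates how fast a particular
route declines. `q` is pinned at 1 during the four baseline weeks and the
increments are defined for weeks 5 onward: letting decline parameters act
during the designated baseline would contradict the baseline's purpose.
Covariates are the route's trip-weighted distance quartile (three
indicators, Q2 = medium distance as reference), the origin zip's
proportion of higher-income subscribers, its county case rate relative to
the population-weighted city mean that week (the only time-varying
covariate; the week-t value multiplies the whole cumulative sum, as the
formula states), and standardized median household income. The reference
age group (18–34) has `beta_a = 0`; no global intercept appears inside
the exponent because it would trade off freely against the scale of `c`.

### Baseline-rate structure

By default one per-subscriber baseline rate is learned per *unordered*
pair and age group (`rate_structure="pooled"`). The directed alternative
(`"directed"`, distinct `r_ija` and `r_jia`) contains the pooled model as
a special case but is only weakly identified: the observations pool
directions, so the per-pair split behaves as an incidental nuisance
parameter whose freedom to chase Poisson noise systematically inflates
the coefficients that differentiate directions (in recovery experiments
at 20 zips, the income effect was biased upward by about +0.09 under the
directed structure and by under +0.01 under the pooled one). The pooled
structure is therefore the package's default inferential model; the
directed structure remains available for simulation-consistency checks
and is what the gravity variant uses (a gravity rate is inherently
directed through origin subscribers and destination population).

### Priors and inference

MAP estimation with weakly informative Normal priors, all centered on "no
effect":

| block | prior | default rationale |
| --- | --- | --- |
| log r | Normal(log empirical baseline rate, 1) | centers each route on its observed February level |
| log c | Normal(-3, 1.5) | c ≈ 0.05 a priori, weak |
| beta, beta_a | Normal(0, 1) | unit-scale covariates |
| beta0 (summer) | Normal(0, 2) | broad global level |
| gravity (log θ, α, δ, γ) | Normal(0, 5) | near-flat |

`PriorConfig.flat_priors()` switches every prior off (maximum
likelihood), used by the exactness tests where the generative truth must
be a stationary point.

Optimization is L-BFGS-B on the full parameter vector with analytic
gradients (the kernel accumulates per-cell derivative weights into the
rate, increment and coefficient blocks; gradient correctness is tested
against finite differences). Deterministic initialization: rates at their
empirical baseline values, c at 0.05, coefficients at 0. Convergence is
reported as the sup-norm of the gradient at the returned point.

Uncertainty is a Laplace approximation: the Hessian of the negative log
posterior at the mode is formed by central differences of the analytic
gradient (step `1e-5 · max(1, |x|)`, symmetrized) and inverted; reported
SDs are square roots of the diagonal, so coefficient uncertainty accounts
for coupling with the baseline rates and weekly increments. A
non-positive-definite Hessian is jittered once and otherwise yields NaN
SDs with a warning rather than a silent answer.

The reported log-likelihood excludes the prior. BIC is
`k ln(n) - 2 log L̂` with `n` the number of (unordered pair, age, week)
cells, censored cells included, and `k` every fitted parameter (baseline
rates included for the free model, the four gravity parameters for the
alternative).

## Summer model

`λ_ija = n_weeks · exp(-(beta0 + beta' X_ij + beta_a)) · r_ija`, fitted to
one aggregated count per route and age over the summer window, with the
decline fit's baseline rates plugged in as fixed values (their
uncertainty is not propagated; the fit's metadata flags this). `n_weeks`
counts the non-missing weeks. When aggregating weekly data, censored
weekly cells contribute the midpoint 25 (a `drop` policy is the
sensitivity toggle); a route is censored only if every week was, in which
case its bound scales to `n_weeks · 49`. There is no case-rate covariate:
the block is treated as a single stable period.

## Descriptive metrics

All series divide a stratum's weekly trips by its own mean weekly
baseline total, so the baseline-period mean is exactly 1 by construction.
Censored cells enter descriptive totals at the midpoint 25 by default
(with `drop` as sensitivity); the imputation choice cannot be checked
against the withheld values, which is why the models, not the
descriptives, carry the inferential weight. The income-ratio series
splits zips at the city median proportion of higher-income subscribers
and reports the ratio of the above-group's relative outward trips to the
below-group's; outward trips are attributed to the recorded origin zip,
ignoring the direction ambiguity at the descriptive level. City-level
correlation of window-mean mobility with window-mean stringency or case
rate is plain Pearson correlation across cities.

## Synthetic data

`SimConfig` defaults define the reference study conditions: 20 zips
placed uniformly in a 40 km square, census populations lognormal with
median 6,000, subscriber counts at 30% of population skewed toward older
groups (shares 0.25/0.35/0.40), a Beta(6, 4) proportion of higher-income
subscribers independent of the zip's median income, nine weekly frames
with a four-week baseline, censoring at 50, and counties as longitudinal
bands carrying exponentially growing case rates with lognormal
county-week noise. Baseline directed rates follow the gravity law
(θ = 5e-3, α = δ = 0.5, γ = -1.2, giving typical pooled route counts in
the low hundreds) times lognormal route noise with SD 0.5 — the route
heterogeneity that the free-baseline model captures and the gravity model
cannot. True decline effects: c = (0.12, 0.12, 0.10, 0.08, 0.06)
(cumulative 0.48, bottoming near half of baseline, the magnitude typical
of hard-hit cities), distance-Q4 effect 0.5, income effect 0.4, case-rate
effect 0.1, age offsets (0, -0.05, -0.1). Summer truth is U-shaped in
distance (Q1 = Q4 = 0.3), income 0.4, intercept 0.2 over 13 weeks. All
draws flow through one PCG64 generator seeded from `SimConfig.seed`
(panel streams use `SeedSequence((seed, k))`), so identical configurations
are bit-for-bit reproducible.

What the generator does *not* emulate: road networks and commuting
structure, day-of-week effects, operator sampling bias beyond the age
skew, spatial correlation of route noise, and daily-level censoring
before weekly aggregation (panels are censored at the weekly cell, the
resolution at which the models consume them). Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to every artefact of real operator
feeds.

## Numerical and design choices

- Distances are haversine on centroids with R = 6371 km; a planar
  projection was rejected for generality.
- Trip-weighted distance quartile boundaries are the smallest distances
  at which the cumulative trip-weight share reaches 1/4, 1/2, 3/4;
  censored cells weigh threshold/2 = 25. Weighting can use the whole
  panel (default) or the baseline month only; the synthetic generator
  defines truth quartiles from expected baseline trips, so recovery
  studies weight by the baseline month. Fewer than two distinct distances
  is an error; fewer than four warns of empty bins.
- Within-zip movement (i = j) is excluded everywhere.
- Weekly aggregation censors a week if any contributing day was censored
  (the partial sum is discarded: it is a bound, not an observation).
- The exponent `beta' X + beta_a` is clipped at ±40 before
  exponentiation to guard overflow; Poisson means are floored at 1e-300
  inside logs.
- Mean-mode simulation (counts set to their expectations, real-valued)
  exists so that exactness tests can assert stationarity of the truth at
  machine precision; the Poisson log-pmf accepts real-valued counts for
  this purpose.
- Problem sizes in the test suite (20-zip recovery replicates, 12-zip BIC
  studies, 8-zip fixtures) were chosen as the smallest cities at which
  the estimators' asymptotics visibly hold; they keep the full suite
  around a minute on one CPU.

## Known limitations

- MAP with priors is a pragmatic substitute for integrating the baseline
  rates out as random effects; the pooled rate structure removes the
  incidental-parameter bias that motivates such integration here, but a
  marginal-likelihood treatment would be the fuller solution.
- Plug-in baseline rates understate summer-model uncertainty.
- The descriptive handling of censored cells (midpoint 25) is one of
  several defensible conventions and materially matters only when the
  censored fraction is large.
- Single-city scope per fit; multi-city analyses loop cities and compare
  outputs, mirroring the per-city modelling design.
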