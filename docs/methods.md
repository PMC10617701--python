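# Methods

This note records the estimators, conventions and synthetic-data model
implemented in `healtheq`, including the numerical choices that matter for
reproducing its outputs.

## 1. Outcome and data layout

The outcome `h ∈ {0,1}` is *comprehensive knowledge*: five ternary interview
items (yes / no / don't know), coded correct when items 1–3 are "yes" (two
prevention methods and "a healthy-looking person can be infected") and items
4–5 (two misconceptions) are "no".  "Don't know" counts as incorrect.
Respondents who never heard of the disease are assigned `h = 0`, so the
indicator is defined on the full sample.  Analyses use the canonical table
columns `h`, `weight`, `cluster`, `stratum`, `wealth_score` plus declared
covariates; rows with missing values in analysis columns are removed by
listwise deletion before estimation.

## 2. Ranks, curve, indices

All moments are weighted with population-form denominators:
`mean_w(x) = Σ w_i x_i / Σ w_i`, `cov_w(x, y) = mean_w(xy) − mean_w(x) mean_w(y)`.

**Fractional rank.**  Sort by wealth score ascending; observations with tied
scores form a block and all receive the block's midpoint cumulative-weight
rank `(W_before + ½ W_block) / W`.  The weighted mean rank is exactly ½.

**Concentration curve.**  Points `(p_j, L_j)` are cumulative population and
outcome weight shares at the end of each distinct-score block, with `(0, 0)`
prepended.  Because the curve is piecewise linear between block endpoints,
the trapezoid area is exact and `C = 1 − 2 ∫ L dp` agrees with the
covariance formula to rounding error; the test suite enforces agreement to
1e−9 on random tables.

**Indices.**  `C = 2 cov_w(h, r) / μ` and the Erreygers corrected index
`E = 4 μ C = 8 cov_w(h, r)` (for a binary outcome, bounds cancel to this
form).  When `μ = 0` the package returns `E = 0` with `C` undefined (NaN)
and a warning, since no outcome weight exists to concentrate.

## 3. Decomposition

A logit model `P(h=1|x) = Λ(β₀ + Σ β_k x_k)` is fitted by weighted maximum
likelihood (IRLS, tolerance 1e−8, max 100 iterations; non-convergence
raises, and |coefficient| > 15 triggers a separation warning).  Collinear
design columns are dropped greedily before fitting, preserving earlier
columns.

Average marginal effects: for a 0/1 indicator column, the average discrete
change `β^m_k = mean_w[Λ(η_i + (1−x_ik)β_k) − Λ(η_i − x_ik β_k)]`; for a
continuous column, `β^m_k = mean_w[Λ'(η_i)] β_k`.

Each design column contributes

```
a_k = e_k · C_k = 8 β^m_k cov_w(x_k, r),   e_k = 4 β^m_k x̄_k,
C_k = 2 cov_w(x_k, r) / x̄_k,
```

with percentage contribution `100 a_k / E` and residual `E − Σ a_k`.  The
adding-up identity holds exactly by construction (tested at 1e−12).  Columns
are grouped back to their declaring covariate for group-level percentages.
The decomposition refuses |E| < 1e−6: percentage shares of a
numerically-zero index are meaningless.

## 4. Uncertainty and trend

Standard errors and 95% percentile intervals come from a stratified cluster
bootstrap: within each stratum, clusters are resampled with replacement
(same number as observed), and the statistic recomputed on the stacked
respondents with their original weights.  Default B = 1000; the coverage
test uses B = 200 and verifies ≥ 90/100 nominal-95% coverage at n ≈ 2,000.
Trend across rounds is ordinary least squares of the index on survey year
(`scipy.stats.linregress`), reporting slope per year and Pearson r; at least
two distinct years are required.

## 5. Wealth index

When only raw asset indicators are available, the wealth score is the first
principal component of the weighted correlation matrix of assets (columns
standardised by weighted mean/SD; constant columns dropped with a warning).
Loadings are oriented so their sum is positive, making higher scores mean
more assets.  Weighted quintiles assign each distinct-score block to the
quintile containing the *start* of its cumulative-weight interval (a tied
block straddling a boundary goes to the lower group), with an `isclose`
guard against floating-point jitter at exact fifths.

## 6. Synthetic data generator

Surveys are generated from a YAML-serialisable configuration:

- **Design.**  `n_strata` strata × `clusters_per_stratum` clusters ×
  `households_per_cluster` respondents.  Each stratum has a selection
  probability; sampling weights are its reciprocal (scaled), so weighted
  estimates target the unequally-sampled population.
- **Latent SES.**  `s_i = m_stratum + u_cluster + ε_i`, with
  `u ~ N(0, σ_cluster²)`, `ε ~ N(0, σ_household²)`.
- **Assets and wealth.**  Asset indicators are Bernoulli in `s` through
  per-asset offsets/loadings; `wealth_score` is a noisy affine image of `s`,
  and weighted quintiles of it define the `wealth` covariate.
- **Covariates.**  Bernoulli or ordered-categorical in `s` (threshold
  models), so education, media exposure etc. correlate with wealth the way
  the outcome model needs.
- **Outcome.**  `h ~ Bernoulli(Λ(β'x))` on the *exact encoded design the
  analyst fits* (including quintile dummies), so the analysis model is
  correctly specified and marginal effects are recoverable.  `heard` is 1
  whenever `h = 1`, otherwise Bernoulli with a high base rate; item
  responses are back-filled consistently with `h`.
- **Determinism.**  Every random quantity draws from a named stream seeded
  by `SeedSequence([seed, sha256(name)])`; identical seeds give
  byte-identical CSVs, and adding a covariate leaves earlier columns
  unchanged.

`population_truth(config, n_draws)` computes large-sample prevalence, index
and average marginal effects on an equal-probability population draw, using
the conditional success probability instead of realised outcomes to remove
outcome-level Monte-Carlo noise.  It is the oracle for the parameter-recovery
tests (5 replicates of n = 20,160 must agree within 3 Monte-Carlo SEs).

### Calibrated fixtures

`calibrate_to_paper(year)` loads one of three packaged configurations
(2005, 2011, 2016) whose intercept and coefficient scale were iterated until
the large-sample prevalence and Erreygers index hit published estimates for
this survey series (19.8% / 0.251, 25.9% / 0.239, 27.9% / 0.201).
Verification on an independent seed at n = 400,000 reproduced all six values
within ±0.001.  The fixtures use 6 strata × 25 clusters × 30 households
(n = 4,500) by default; tests and the acceptance script scale
`clusters_per_stratum` to trade precision against runtime.

## 7. Problem sizes and tolerances

Chosen to keep the full suite under a few minutes while leaving tolerances
honest (3 Monte-Carlo SEs or analytic exactness, never tuned to outcomes):
random-table oracle checks n ≤ 50 × 1,000 tables at 1e−9; identity checks at
1e−10…1e−12; recovery at n = 20,160 × 5 seeds; calibration checks at
n = 400,000 population draws (prevalence ±0.01, E ±0.02); bootstrap coverage
at n = 2,016, B = 200, 100 replications, threshold 90/100.
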