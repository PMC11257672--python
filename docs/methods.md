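# Methods

`raincross` implements a two-stage analysis of the short-term association
between cumulative precipitation and daily diarrheal mortality, pooled by
first-level climate zone (tropical / arid / temperate), together with a
synthetic-data generator that makes every stage testable against known
truths.

## First stage: time-stratified case-crossover, conditional quasi-Poisson

For each within-country climatic region (a "location"), daily death
counts Y_t are modelled as

    ln E[Y_t] = alpha_c + f(rain_t; beta) + s(temp_t, l; theta) + I(month_t; gamma)

where

* `alpha_c` is an intercept for the time stratum c = (year, quarterly
  month block, day of week). Comparing a death day only against the
  other same-weekday days of its quarter self-matches out seasonality,
  long-term trend and weekday patterns; each case day has roughly 12
  control days.
* `f` is a natural cubic spline of the exposure `rain_t`, the running
  sum of daily precipitation over the `window` = 28 days strictly
  preceding day t (the death day itself is excluded). Internal knots sit
  at the 50th and 90th percentiles of the exposure distribution —
  asymmetric on purpose, because daily precipitation is right-skewed —
  and boundary knots at the observed min/max. The basis carries no
  intercept (absorbed by `alpha_c`), so with two internal knots the
  coefficient vector beta has k = 3 entries.
* `s` is a bidimensional exposure–lag cross-basis for daily mean
  temperature over lags 0–28: a natural spline over temperature (knots at
  the 33rd/67th percentiles) tensored with a natural spline over lag
  (intercept plus three internal knots equally spaced on the log-lag
  scale, i.e. 28^{1/4}, 28^{1/2}, 28^{3/4}). Column (j,k) at day t is
  `sum_l v_j(temp_{t-l}) w_k(l)`.
* `I` is a set of eleven calendar-month indicators (January reference),
  capturing residual within-quarter monthly variation.

Fitting conditions on the stratum totals. For a Poisson likelihood the
stratum intercepts have a closed-form profile,
`alpha_c = log(sum_c y / sum_c exp(x'beta))`, so the solver alternates
exact intercept profiling with an IRLS step in which the working
response and design are weighted-centered within strata. The fixed point
is identical to a Poisson GLM with one explicit dummy per stratum — that
dummy fit (statsmodels) is the test oracle, with agreement required to
1e-6 — but never materialises the dummies. Convergence is declared when
the relative deviance change falls below 1e-9 (absolute floor 1e-12 for
saturated toy problems), with at most 50 iterations; non-convergence
raises an error carrying the deviance trace.

Two structural details matter in practice:

* **Aliasing.** Quarterly blocks are month triples under every offset, so
  three combinations of month dummies are exactly collinear with the
  stratum space. Columns that lose all within-stratum variation after
  centering are detected by an order-preserving Gram–Schmidt sweep and
  dropped, mirroring what dummy-variable GLM software does silently.
  Dropping a precipitation-basis column is an error, never silent.
* **Overdispersion.** The coefficient covariance is the inverse Fisher
  information scaled by the Pearson dispersion
  `phi = sum (y-mu)^2/mu / (n - p - n_strata)`. Strata with zero total
  deaths contribute nothing to the conditional likelihood and are
  dropped before any of this.

Only the precipitation block (beta, its k×k covariance) feeds the second
stage; temperature and month coefficients are nuisance.

## Second stage: multilevel multivariate REML meta-regression

Location coefficient vectors are pooled under

    beta_{i,j} = X_{i,j} gamma + g_j + e_{i,j},   g_j ~ N(0, Psi),  e_{i,j} ~ N(0, S_{i,j})

with X encoding climate-zone fixed effects (reference level plus
contrasts, each a full k-block; optionally a centered continuous
meta-predictor interacting with the block) and g_j a country-level
random coefficient vector shared by all of country j's locations.
Psi (unstructured k×k) is estimated by REML over its Cholesky factor
(Nelder–Mead polished by BFGS, two starts: near-zero and a
method-of-moments matrix); gamma and its covariance follow by GLS at the
REML Psi. If the unstructured optimum is numerically rank-deficient the
model is refit with a diagonal Psi and the fit record says so. The
implementation reproduces `metafor::rma.mv(..., random = ~outcome|country,
struct = "UN")` to ~1e-5 on a frozen reference dataset.

Heterogeneity and inference:

* Cochran's Q is computed at the fixed-effect (Psi = 0) GLS solution,
  `Q = sum r' S^{-1} r`, df = Nk − p; I² = max(0, (Q − df)/Q) × 100.
* The climate effect is tested by a Wald chi-square on the full contrast
  block (df = k × (levels − 1)).
* BLUPs: `g_j = Psi Z' V_j^{-1} (y_j − X_j gamma)` from all of country
  j's locations jointly; a location's BLUP is its fixed prediction plus
  g_j. The reported BLUP covariance combines fixed-effect uncertainty
  with the conditional variance of g_j; the cross term is ignored, a
  deliberate simplification that slightly understates the covariance.

**Common basis.** Coefficients are only poolable on a shared basis, so by
default (`knot_sharing="per_climate"`) every location's precipitation
spline is built with knots at the *climate-pooled* exposure percentiles
(usable-day 28-day sums concatenated across the climate's locations, so
each location weighs in by its person-days). `per_location` knots are
available as a config switch for sensitivity work, accepting the usual
two-stage approximation when bases differ.

## Risk summaries

A coefficient vector is turned into a curve by contrasts:
`log RR(x) = [b(x) − b(ref)]' beta`, `se² = c' V c`, 95% CI via exp(±1.96 se)
(normal multiplier; no small-sample correction). The minimum-risk
precipitation (MMP) is the argmin of log RR over [min, P90] of the
exposure distribution, searched on a 1-percentile grid and refined to
0.1 percentile around the coarse argmin, ties toward drier. Headline
summaries recentre the curve at the MMP and report the percent change
(exp(logRR) − 1) × 100 at the 5th ("extremely dry") and 95th ("extremely
wet") percentiles. Pooled climate curves use the climate-pooled
percentile table; country-climate BLUP curves use the country's own.
Curves are reported on a 100-point percentile-spaced grid plus the exact
5th/50th/95th points.

With knots only at P50/P90, mid-distribution curvature is resolved
coarsely: the best-approximating spline of a quadratic log-RR has its
vertex displaced by several percentiles. This is a property of the basis
choice, visible in the tests, and the reason qualitative MMP checks use
windows rather than exact equality.

## Aggregation and inclusion

Unit-level series (smallest administrative level) are grouped by
(country, Köppen sub-climate): deaths summed per day; weather averaged
across units with each unit's whole-period death total as a
time-constant weight (the weighting window is a design choice — the
per-day alternative would let weights vary with reporting noise).
First-level climate comes from the sub-climate's initial letter
(A/B/C → tropical/arid/temperate); cold and polar units (D/E) are
rejected because the analysis domain excludes them. A region enters the
analysis only if every calendar month in its span records at least one
death; exclusions are reported with the first failing month.

## Synthetic-data generator

The generator is first-class code: it defines the study conditions under
which every recovery claim is tested.

* **Precipitation**: seasonal wet-day Bernoulli times gamma intensity
  (right-skewed), both modulated by an annual sinusoid. Presets give
  annual totals ordered tropical (~6,400 mm, monsoon-like so 28-day sums
  reach into the thousands of mm) > temperate (~1,240 mm) > arid
  (~440 mm).
* **Temperature**: annual sinusoid plus Gaussian noise (tropical 27±2 °C,
  arid 23±8 °C, temperate 15±9 °C).
* **Deaths**: negative binomial with mean mu_t and variance phi·mu_t
  (Poisson at phi = 1; default phi = 1.5), with
  `log mu_t = log(baseline) + logRR(cum_t) + temp_effect · z_t`, where
  z_t is the standardized 29-day trailing mean temperature (a nuisance
  the cross-basis must absorb; default amplitude 0.05). Baseline is 8
  deaths/day — a mid-sized region's count, large enough for stable
  per-location fits at 10 years.
* **Truth curves**, anchored to frozen long-run (400-year) percentiles of
  each preset's 28-day sums: tropical log-linear with RR = 1.18 at P95
  vs the minimum; arid quadratic with vertex at P73 and RR = 1.055 at
  P5; temperate quadratic with vertex at P64 and RR = 1.038 at P5.
  These effect sizes and shapes track the published magnitudes for the
  three zones (≈+18% tropical wet, ≈+4–6% arid/temperate extremes).
* **Between-country heterogeneity**: one Gaussian draw per country
  (sd 0.05 on the log-RR scale at the curve's anchor extreme) added to
  the curve coefficient — exactly the additive coefficient-level random
  effect the second-stage model assumes.

What the generator does *not* emulate: spatial correlation between
locations, monsoon onset dynamics or ENSO, reporting gaps, secular
trends in baseline mortality, or pathogen-specific exposure lags.
Passing recovery tests therefore demonstrates internal statistical
correctness of the two-stage machinery under its own assumptions, not
robustness to those real-data features.

## Problem sizes and numerical choices

Monte-Carlo tests run at the study's own scale — 29 locations, 8
countries, 10 years — with 10 replicate studies for coverage/power and
50 smaller single-climate studies for the qualitative MMP checks; these
sizes keep the default test run within a few minutes while leaving the
binomial success criteria meaningful. Determinism: every random draw
flows from a single `numpy` Generator seed; the pipeline itself is
deterministic, and rerunning with the same config and input yields
byte-identical JSON artifacts (floats written with `%.17g`, exact
round-trip on read).

Known limitations: BLUP covariances omit the fixed/random cross term;
the REML surface can have boundary optima (handled by the diagonal
fallback, recorded in the manifest); quarterly strata at series edges
(partial quarters) are kept; and the "1 case : 11 controls" ratio is a
property of the calendar, not enforced.
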