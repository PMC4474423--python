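# Methods

## Model

For a gene pair (i, j) in a cohort of K samples, the per-sample
covariability is the product of the two genes' expression z-scores,
C_ijk = z_ik · z_jk. Z-scores use the sample standard deviation
(K−1 denominator), so the identity Σ_k C_ijk = (K−1)·r_ij holds with r the
Pearson correlation; the convention is exposed as
`comre.covariability.PEARSON_DDOF`. With the population convention (ddof=0)
the sum would instead equal K·r and individual C values would shrink by
(K−1)/K; the sample-sd choice keeps per-sample values on the scale at which
single outlying samples produce covariability magnitudes of order K, which
is the behaviour the statistic is designed to expose.

Each pair's covariability vector is regressed on the z-scored expression of
M candidate modulators by ordinary least squares:

    C_ij = β0 + Σ_m β_m z(e_m) + ε.

Assumptions inherited from OLS: approximately independent modulators
(enforced — a condition number of XᵀX above 1e8 is a hard
`RankDeficientError`, never a silent ridge), homoscedastic errors, and
enough degrees of freedom (K > M + 1). Each coefficient gets a two-sided
t-test with K − M − 1 degrees of freedom.

### Intercept

The bare model formula has no constant term, but a covariability vector has
expected mean (K−1)·r/K per sample — generally nonzero — so omitting the
intercept would bias every β toward absorbing the pair's baseline
correlation. The intercept is therefore included by default and excluded
from significance testing; `--no-intercept` (or `intercept=False`) fits the
literal formula, with K − M degrees of freedom.

### Batching

The design matrix does not depend on the pair, so the projector
(XᵀX)⁻¹Xᵀ and the diagonal of (XᵀX)⁻¹ are computed once; covariability rows
are formed and fitted in chunks (default 10,000 pairs) as plain matrix
products. Batched results are identical to per-pair fits to 1e-10 (tested).
A perfect fit (zero residual sum of squares) makes the t-statistic
undefined; the p-value is then set to 0 for coefficients whose magnitude
exceeds 1e-10 relative to the response scale and 1 otherwise.

## Significance calling and grouping

A modulator is significant for a pair when its p-value is strictly below α
(default 0.05). Pairs are partitioned by their exact significant-modulator
set; the partition is exhaustive, includes the empty signature ("none"), and
is ordered by size descending with lexicographic signature tie-breaks.
"Core" pairs of a group are those whose signature modulators all satisfy
p × family < α; the family size defaults to the number of pairs tested — the
most conservative reading — and is configurable, as is an any-modulator rule.
Node degree of a gene is its number of partners within a group's pair graph;
hub rankings break degree ties lexicographically.

Modulator co-occurrence uses the two-sided Fisher's exact test
(point-probability rule: the sum of hypergeometric probabilities no larger
than that of the observed table) on the 2×2 classification of all pairs by
significance for each of the two modulators, via `scipy.stats.fisher_exact`;
tests verify it against exact rational-arithmetic enumeration on every table
with n ≤ 40. Direction (positive/negative) compares the observed both-count
with its expectation under independent margins; a degenerate margin yields
p = 1 with a warning. Proportion confidence intervals are plain 95% Wald
intervals, p̂ ± 1.96·√(p̂(1−p̂)/N), unclipped unless requested, matching the
convention used for reporting validated-patient fractions.

## Cross-cohort validation

Discovery betas are applied unchanged to the validation cohort's modulator
z-scores — recomputed within the validation cohort, since platforms and
scales differ — to produce each patient's estimated covariability profile
across a pair subset; the intercept is included by default (configurable).
The real profile comes from the validation cohort's own expression. A
patient validates when the Pearson correlation between the two profiles
across pairs is positive with two-sided p < 0.05; this operationalizes
"significantly positively correlated" while keeping the standard two-sided
test, so the chance rate in null data is ~0.025 (the positive half of the
5% two-sided tail). The default pair universe is every pair with at least
one significant discovery modulator; any signature group can be selected
instead. The overall one-sample z-test is one-sided (is the validated
proportion greater than the null proportion p₀, default 0.05?), with
z = (p̂ − p₀)/√(p₀(1−p₀)/N).

## Synthetic cohorts

`generate_null` draws i.i.d. Gaussian log2-like expression (mean 8, sd 1 —
a typical microarray log2 intensity scale) with no structure; it is the
random-baseline control and the type-I-error calibration input.

`generate_modulated` plants modulator-dependent correlation: modulator
z-scores are i.i.d. standard normal, each planted pair's per-sample target
correlation is the linear predictor ρ_k = clip(baseline + Σ β_m z_mk,
±0.99), and the pair's two values in sample k are a bivariate normal draw
with correlation ρ_k. The linear-with-clipping link (rather than tanh) keeps
planted betas on the scale the regression estimates, making recovery a fair
test; clipping events are counted and warned about. Genes appear in at most
one planted pair so replicates are independent. All draws flow from one
seeded generator; outputs are bit-identical under a fixed seed.

What the generator does *not* emulate: probe-level artifacts, batch
effects, heavy-tailed or skewed expression, correlated modulators, and
background co-expression among unplanted genes. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the model's own assumptions, not robustness to real-microarray pathology.

`scenario_with_random_effects` builds recovery/validation scenarios: N
disjoint planted pairs, effect magnitudes uniform in [0.2, 0.5] with random
signs. Magnitudes are bounded away from zero so every planted pair carries
detectable signal, and effects vary across pairs so per-patient predicted
profiles are non-degenerate — both needed for a meaningful cross-cohort
correlation. An `effect_seed` separate from the cohort seed lets two cohorts
share identical ground truth.

## Preprocessing

Probe-level matrices are collapsed to one row per gene by keeping the probe
with the largest coefficient of variation (sd/mean on log2 values, sample
sd; the ddof is a parameter since published thresholds rarely state it).
CV ties go to the lexicographically smallest probe id for determinism.
Rows with CV < 5% or mean log2 expression < 6 are then removed (retention
uses ≥, mirroring strict-< removal wording); both operations are idempotent
and order-preserving. Missing or non-numeric cells are rejected at load time
with their location — covariability and OLS assume complete data, and
imputation is out of scope.

## Problem sizes used in the test suite

The suite exercises the pipeline at desk scale: null calibration pools
1,225 pairs × 10 modulators at K = 200; parameter recovery uses 100
replicate pairs at K = 300 with β = 0.3; cross-cohort validation uses 250
planted pairs, 3 modulators and K = 250 per cohort. These sizes give
Monte-Carlo standard errors small enough for 3-sigma assertions while the
whole suite completes in well under a minute of compute for the statistical
tests; the Fisher enumeration over all 2×2 tables with n ≤ 40 dominates the
runtime. The batched regression itself handles genome-scale pair counts by
streaming chunks; `count_pairs(5308) = 14,084,778` pairs at K = 286 is a
few hundred seconds of matrix products at the default chunk size.

## Known limitations

* Modulation, not causation: a significant β says the pair's co-variation
  tracks the modulator's expression, not that the modulator drives it.
* Modulators are assumed (and required) to be numerically independent;
  correlated candidate panels need care — the hard collinearity error is
  deliberate.
* The covariability of overlapping pairs (sharing a gene) is dependent, so
  pooled counts of significant calls are not independent draws; binomial
  error bars on pooled rates are approximate.
* The Bonferroni family for core pairs is a convention (the number of pairs
  tested, per modulator); other families change core counts substantially.
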