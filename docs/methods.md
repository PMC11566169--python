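# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Variable coding

The ten binary social-activity items sum to a 0–10 participation count.
Family participation counts active aspects — parent care (any positive
weekly hours), grandchild care (ever), housework help (any frequency
above "almost never") — capped at 2.

Two boundary conventions are configurable because the questionnaire's
published band edges overlap:

* **CES-D bands** (9-item version, total 0–27): default cuts `(10, 18)`,
  i.e. ≤ 9 → 0, 10–17 → 1, ≥ 18 → 2, so the bands partition the range
  (the raw description places 17 in two bands).
* **Income brackets** (annual RMB): half-open `[lo, hi)` at 2,300 /
  5,000 / 10,000 with the top bracket closed above, again to remove the
  printed endpoint overlap.

Missing income is preserved through coding (`income_code = NA`) and
handled downstream: the regression deletes listwise (income enters as a
control, so its analysis n is much smaller), the intersectional models
never use income directly, and the SES latent-class model recodes
missingness as an explicit fifth income level so that every respondent
receives an SES class without imputation. The neutral profile score
assigned to that level keeps class orientation (high vs low) driven by
the substantive levels.

The MAIHDA outcome is the z-scored participation count (sample mean 0,
SD 1, ddof = 1) computed on the analysis sample; the raw 0–10 scale is
available by config. Rationale: stratum-level results on a standardized
scale (residual variances near 0.88, stratum means spanning roughly
−0.5 to 0.8) are the convention this analysis family reports, while raw
counts average near 2.7.

## Latent class analysis

Model: mixture of conditionally independent categorical indicators,
K classes; parameters (π, ρ) estimated by EM. Numerical choices:

* Initialization from Dirichlet(1) random responsibilities; 20 seeded
  restarts by default, best log-likelihood kept (1 suffices for K = 1,
  whose MLE is the marginal frequencies).
* Convergence when |Δℓ| < 1e-6, cap 1,000 iterations; non-convergence
  returns `converged=False` with a warning rather than raising.
* Item-response probabilities floored at 1e-6 (renormalized) so sparse
  cells cannot produce −∞ log-likelihoods.
* Model choice minimizes BIC, ties toward fewer classes; the pipeline's
  composites are binary by design, so if BIC ever preferred K ≠ 2 the
  K = 2 fit is still used for assignment (logged).
* Class labels come from the fitted profiles, not class order: the
  class with the lower mean ordinal health profile is "healthy"; the
  class with the higher hukou/education/income profile is "high" SES.
  The mapping is invariant to label switching.

## OLS and propensity-score matching

OLS uses the normal equations with classical homoskedastic SEs and
listwise deletion; rank deficiency raises with the collinear columns
named. The propensity model (treatment = any family participation vs
none) is a logistic MLE by IRLS, converged when the score norm falls
below 1e-8; divergence is reported as suspected perfect separation.

Matching is with replacement: 1-nearest-neighbour (ties to the lower
record index; optional caliper) and Epanechnikov-kernel matching with
default bandwidth 0.06 on the propensity scale, weights normalized per
treated unit. The ATT is the mean treated-minus-matched-controls
difference. Its SE is a seeded bootstrap: when the matcher context is
available (as in the pipeline), records are resampled with replacement
and re-matched on each of B = 200 draws, capturing control reuse and
matching variability; the propensity score is held at its full-sample
fit, a standard practical simplification that tends to be conservative.
With only matched pairs available, the fallback resamples per-treated
differences, which understates design variability and is labelled as
such.

Balance: standardized bias per covariate is 100·(x̄_T − x̄_C)/√((s²_T +
s²_C)/2) with pre-matching group variances in the denominator for both
the before and after columns, so the two share a scale; post-matching
control means use aggregated match weights. Pseudo-R² (McFadden) and
the LR χ² re-fit the propensity model on the weighted matched sample.

## MAIHDA

Strata are the 2 × 2 × 2 × 3 cross-classification of gender (women,
men) × health (healthy, unhealthy) × SES (high, low) × family
participation (none, middle, high), in that lexicographic order, so
women/healthy/high/none is stratum 1 and men/unhealthy/low/high is 24.
Empty strata remain in the model; their effects are drawn from the
prior conditional and are flagged as prior-dominated in summaries.

Two models are fitted: null (intercept + stratum effects) and main
effects (adding male, unhealthy, low-SES and family-participation
contrasts). The family-participation fixed effect defaults to the
binary any-vs-none contrast, matching the single published contrast
row, even though the strata distinguish three FP levels; a three-level
dummy coding is available by config (`fp_fixed_coding="three_level"`).
Which coding produced the published main-effects stratum variance is
not stated in the source analysis; the binary default is ours.

**Priors.** Normal(0, 10²) on the intercept and coefficients;
half-Cauchy(0, 1) on both SDs — a concrete instantiation of "weakly
informative" — implemented through the inverse-gamma parameter
expansion (Huang–Wand), which keeps every conditional conjugate.

**Sampler.** A collapsed blocked Gibbs sampler: the fixed effects are
drawn with the stratum effects integrated out (GLS against the
compound-symmetric stratum marginal covariance), then u | θ, then the
variances with their auxiliaries. Collapsing matters: with few
identifying strata the centered update mixes poorly for the intercept,
while the collapsed chain matches an independent ensemble-sampler
reference on the analytically u-marginalized posterior (see the test
suite). Because covariates are constant within stratum, each iteration
works on per-stratum sufficient statistics and costs O(24) regardless
of n. Defaults: 2 chains, 5,000 warm-up of 10,000 total iterations per
chain, split R-hat threshold 1.05 and bulk ESS via arviz; tests and
demonstrations scale the chains down (typically 1,000 / 2,000) since
the collapsed sampler mixes in far fewer iterations.

**Decomposition.** VPC = 100·σ²_u/(σ²_u + σ²_e) per model and
PCV = 100·(σ²_u,null − σ²_u,main)/σ²_u,null are reported at posterior
means (the convention in this literature) and are available as
posterior distributions; `interaction_share = 100 − PCV` exactly, and
negative PCVs are reported as-is. Per-stratum summaries use equal-tailed
2.5/97.5 posterior percentiles; per draw, expected = x_j'θ,
predicted = expected + u_j, so the posterior-mean identity
predicted − expected = random effect holds to numerical precision. A
stratum is flagged as showing a specific intersectional interaction
when its random-effect interval excludes zero.

## Synthetic data

`generate_two_level` draws directly from the two-level normal model on
the 24-stratum lattice with known fixed effects, stratum variance and
optional per-stratum interaction offsets δ_j — the clean instrument for
sampler-recovery and decomposition experiments.
`additive_effects_scenario` fixes an additive regime (β = 0 / −0.20 /
−0.45 / +0.50 for male / unhealthy / low-SES / any-FP, σ²_u = 0.0196,
σ²_e = 0.8830) in which main effects carry ≈ 85% of the between-stratum
variance — the regime the published decomposition reports.

`generate_survey` produces full raw tables. Latent health and SES
classes and the FP category are assigned by exact-count random
allocation (largest-remainder for the three FP levels): the preset's
targets are a study's *realized* composition, and Bernoulli sampling
would miss them by more than 2% on a non-trivial fraction of seeds.
Indicators are drawn class-conditionally (categorical self-rated
health; CES-D as a rounded truncated normal on [0, 27]; IADL by band
then uniform within band; class-specific hukou/education/income
distributions; income ~60% missing completely at random, echoing the
income-complete subsample being well under half the full sample). The
outcome construction keeps the observable a genuine 0–10 count: the ten
items are conditionally independent Bernoullis whose success
probability is affine in the record's two-level linear predictor
η = γ₀ + x'β + u_j + δ_j + e. The item-level (binomial) noise this adds
is budgeted out of the target SD, so the count calibrates to mean 2.68
/ SD 1.74, but it also means the *observed* count's stratum-level
variance share is diluted relative to η's — an end-to-end run on survey
output therefore shows a lower VPC than the generating σ²_u implies,
and misclassification in the recovered latent classes dilutes it
further. Recovery of the generating variance components is accordingly
tested on `generate_two_level` output, and the survey generator is
tested on marginals, orderings and pipeline closure. Passing tests on
these data show the machinery is correct under the model's assumptions;
they cannot show robustness to real-survey features the generator omits
(cluster sampling and weights, item missingness beyond income,
correlated indicators within class, measurement error).

Interaction-detection demonstrations (a single stratum with δ = +0.3
ranked first) run in a signal-dominant regime (σ²_u = 0.001, so δ is
~6× the competing stratum SD including sampling noise): with
study-scale σ²_u ≈ 0.02 the largest of 23 null stratum effects is
itself comparable to 0.3, and no estimator could rank the injected
stratum first reliably — the demonstrations are about the machinery,
not about power at study scale.

Problem sizes in the test suite are chosen for statistical
informativeness: two-level recovery uses 200 records per stratum
(4,800 total) aggregated over 10 seeds, because with only 24 level-2
units the realized between-stratum variance of a single draw has a
sampling SD near 29% of its target and no single-seed estimate is
meaningful; latent-class selection uses n = 2,000 per replicate; the
matching study uses n = 1,000 per replicate, since the sampling noise
of post-matching standardized bias at a few hundred records is the
same order as the 10% balance criterion itself.

## Known limitations

* Survey weights are not supported; all analyses are unweighted.
* No imputation; missingness handling is limited to the income rules
  above.
* The MAIHDA outcome model is Gaussian only (no binary/logistic
  variant), with exactly the four stated dimensions.
* The ATT bootstrap holds the propensity fit fixed; no doubly robust or
  sensitivity analyses are provided.
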