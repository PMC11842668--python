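# Methods

This note documents the statistical procedures implemented in `iptwkit`, the
defaults chosen where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Setting

The package targets the analysis of a prospective pregnancy cohort (n = 1003)
with a rare binary exposure (first-trimester heated-tobacco-product smoking,
23/1003) and a rare binary outcome (placental abruption, 9/1003). The
exposure–outcome 2×2 published for that cohort (a=2, b=21, c=7, d=973) and
the participant-flow counts are packaged as fixtures; the individual-level
data are not public, so everything beyond the crude contrasts is exercised on
synthetic cohorts with known ground truth.

## Propensity model and weights

The propensity score is fit by maximum-likelihood logistic regression
(statsmodels GLM/IRLS, max 100 iterations, tolerance 1e−8). ATE weights are
`1/e` for exposed and `1/(1−e)` for unexposed rows. Numerical choices:

- fitted probabilities are clipped to `[1e−6, 1−1e−6]` before weighting.
  This prevents infinite weights without materially changing estimates; no
  percentile trimming or stabilisation is applied by default, since raw ATE
  weights are the baseline method being reproduced.
- any coefficient beyond ±15 on the logit scale is treated as
  (quasi-)separation and raises `SeparationError` naming the covariate. With
  only ~23 exposed, covariates with prevalence below ~1% frequently have zero
  exposed carriers and will trip this check — that fragility is a property of
  the data regime, not of the implementation, and is why the Bayesian step
  uses proper (bounded) priors.
- the c-statistic is the rank-based AUC with ties counted 1/2 (equivalent to
  the Mann–Whitney statistic).

## Effect estimation

Both outcome models have the saturated design `(1, Z)`, so the weighted MLE
is the pair of weighted arm means; the implementation evaluates it in that
closed form and assembles the sandwich explicitly:

- bread `B = Σ wᵢ (dμ/dη)²/Vᵢ · xᵢxᵢᵀ`, meat `M = Σ (wᵢ eᵢ (dμ/dη)/Vᵢ)² xᵢxᵢᵀ`,
  covariance `B⁻¹MB⁻¹` (HC0 — no small-sample correction, because the method
  being reproduced specifies plain robust estimates).
- Gaussian/identity for the risk difference; Poisson/log (modified Poisson)
  for the risk ratio, with fitted means clipped to `[1e−10, 1−1e−10]` only
  inside the variance evaluation.
- Wald intervals use the normal quantile (1.959964 at 95%); no t correction.
- weights are treated as fixed: the frequentist analysis deliberately ignores
  propensity-estimation uncertainty, which the Bayesian step then addresses.

With unit weights these reduce exactly to the textbook crude formulas
`SE(RD) = sqrt(p₁q₁/n₁ + p₀q₀/n₀)` and
`SE(log RR) = sqrt((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀))`; the test suite asserts
agreement to 1e−8 on arbitrary 2×2 expansions and cross-checks against
statsmodels' independent HC0 fits.

The crude risk ratio computed from the packaged 2×2 is 12.174. (The
unadjusted risk-ratio value printed in the motivating report, 13.2 with CI
2.6–67.6, is not consistent with its own published counts under any standard
crude formula; only the crude risk difference, 0.0798 → 0.08, is treated as
an exact reproduction target.)

## Two-step Bayesian IPTW

Step 1 samples the posterior of the logistic propensity model:

- intercept: Cauchy prior with scale 2.5 centred at logit(0.126), the assumed
  population HTP-smoking rate. The analogous outcome anchor logit(0.007) is
  carried in `PriorSpec` for reporting; the outcome step itself is
  frequentist per draw, matching the two-step procedure in which weights from
  each propensity draw feed the ordinary outcome model.
- slopes: uniform(−10, 10) on the log-odds scale, sampled through a logistic
  transform to unconstrained space with the Jacobian included.
- sampler: an in-package No-U-Turn sampler (slice-variable tree doubling,
  dual-averaging step size targeting 0.8 acceptance, diagonal metric adapted
  over expanding warmup windows, max tree depth 10). Any MCMC producing ≥2
  independent chains satisfies the module's sampler contract; NUTS is the
  reference because the posterior is smooth and gradients are analytic.
- defaults: 4 chains × 2,500 post-warmup draws (10,000 total) with 1,000
  warmup iterations per chain. Chain count and warmup length are package
  choices; the total draw count matches the reported analysis.

Step 2 computes, for every draw, propensity scores for all rows, ATE weights,
and the weighted RD and RR point estimates (closed-form arm means — exactly
the per-draw GLM solutions). Draws yielding degenerate weighted fits are
dropped and counted; more than 1% dropped raises. The per-scale summaries are
the posterior mean, the 94% highest-density interval (94% matching the
reported interval mass), and the maximum split-R̂ over propensity parameters.

Diagnostics implemented here rather than imported: split-R̂ is the rank-free
variant `sqrt(((n−1)/n·W + B/n)/W)` over half-chains, and the HDI is the
narrowest contiguous window containing `⌈mass·n⌉` sorted draws. The arviz
implementations serve as independent oracles in the tests only.

Interpretation caveat: the two-step posterior spread quantifies propensity
uncertainty only — the per-draw outcome fit contributes no variance — so the
posterior SD on a single cohort can sit far below the sampling SD of the
point estimate. Parameter-recovery tests therefore average posterior means
over replicate cohorts instead of trusting one cohort's HDI as a frequentist
interval.

## Bounding-factor bias analysis

`B = RR_UD·RR_UE/(RR_UD+RR_UE−1)` and `RR_POST = RR_PRE/B`, with both inputs
required ≥ 1 (harmful direction). The grid spans [1, 15] on both axes with
step 0.5 by default (the published figure's resolution is unstated; 0.5 gives
a 29×29 lattice exported as tidy CSV). The E-value solver returns the
continuous closed-form root `x = rr + sqrt(rr(rr−1))` and is reported for
both the point estimate and the CI bound nearer the null — applied to the
published adjusted estimates (11.3, lower bound 7.5) these give 22.09 and
14.48; the headline robustness number is the latter, and it is deliberately
not rounded to the integer quoted in prose.

## Sample-size chain

Two-proportion normal-approximation size with allocation ratio
`(1−exposure_rate)/exposure_rate`, pooled variance under H0 and unpooled
under H1, no continuity correction. The unexposed risk is derived from the
stated mean outcome rate by solving the exposure-weighted mixture
(`p0 = mean − exposure_rate·RD`, default) or taken as the mean directly
(option). Under the stated assumptions (exposure 12.6%, mean rate 0.7%, RD
0.7%, α 0.05, power 0.80) the formula gives 1,530 exposed + 10,608 unexposed
= 12,138 analyzable; a Monte-Carlo z-test oracle confirms ~0.80 power at
those sizes. The published design total (12,836) is reported alongside and
is not reproduced exactly by any standard variant of the formula — the
module never forces agreement. The attrition inflator divides by the product
of retention multipliers (0.70 × 0.20 × 0.70 = 0.098) with an epsilon-guarded
ceiling.

## Synthetic-data generator

What it emulates: binary covariates with the motivating cohort's baseline
marginal prevalences; a logistic exposure model; a log-risk (multiplicative)
untreated outcome model; a constant additive exposure effect. Intercepts are
calibrated *exactly* to target marginal rates by enumerating the distribution
of the covariate score (covariates are independent, so the enumeration is a
binary convolution). Potential outcomes share one uniform draw per subject
(monotone coupling), making the true ATE equal to the configured risk
difference by construction. One root seed spawns independent streams for
covariates, exposure and outcomes; identical configurations are reproducible
byte-for-byte. A guard warns (not errors) when the expected case count falls
below 5.

Defaults: `default_config()` mirrors the study regime (n=1003, exposure
2.3%, baseline outcome 0.7%, effect RD 0.07, 16 covariates). The covariate
set follows the published baseline table; the near-deterministic
"pre-pregnancy HTP use" row (21/23 among the exposed) is excluded because it
would make the default propensity model practically separated. Outcome
log-risk effects are kept modest (positive effects summing to ≈3.6) because
the log link must keep `p0(x) + RD ≤ 1` for *every* covariate pattern — the
configuration validator enforces this and names the offending pattern.

`confounded_config()` is the estimator-validation scenario: two strong
confounders (risk/odds ratios 8 and 3) and the general-population exposure
prevalence of 12.6%. Validation of coverage and bias needs the asymptotic
regime; at 2.3% exposure a cohort of 5,000 carries only ~9 exposed cases and
95% Wald intervals cover near 83% — a rare-event limitation of
normal-theory intervals (it persists with *true* weights), not an estimator
defect. Under the 12.6% scenario the measured operating characteristics over
replicates are: IPTW mean bias < 0.001, crude confounding bias ≈ +0.010,
and 95% CI coverage ≈ 0.93.

What the generator does **not** emulate: covariate dependence (marginals only
— joint correlations of the real cohort are unpublished), survey sampling and
attrition mechanisms, fraud filtering, missing data (the source questionnaire
forced complete responses), continuous covariates, or effect heterogeneity.
Passing tests therefore demonstrate estimator correctness under the assumed
data-generating model, not robustness to misspecification.

## Problem sizes used in the automated checks

Full-scale Bayesian runs use the complete 4 × 2,500-draw budget on n=1000
cohorts. Replicate-based validation uses 200 cohorts (bias) and 500 cohorts
(coverage) of n=5,000, and 12 replicate two-step runs at reduced draw budgets
for Bayesian recovery — sizes chosen so the Monte-Carlo error of each check
sits well below the tolerance it asserts.

## Known limitations

- Wald/sandwich intervals undercover when exposed-case counts are in the
  single digits (measured above); the Bayesian two-step and the bounding
  factor analysis are the package's answers to that regime, as in the
  motivating analysis.
- The fixed-weight sandwich ignores propensity-estimation variance by design.
- The modified Poisson route requires at least one case per arm; cohorts
  violating this raise rather than return degenerate estimates.
- Separation handling is detection-and-refusal (no Firth or penalised
  fallback); choose the propensity covariate subset accordingly.
- The NUTS implementation uses a diagonal metric; heavily correlated
  posteriors would mix more slowly than with a dense metric, though the
  logistic propensity posteriors here mix with split-R̂ ≤ 1.01 at the default
  budget.
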