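# Methods

## Statistical model

`mrkit` operates on summary statistics of two non-overlapping GWAS samples of
the same ancestry. For instrument Gⱼ (j = 1..k) the exposure sample supplies
(β̂ⱼₓ, var(β̂ⱼₓ)) and the outcome sample (β̂ⱼᵧ, var(β̂ⱼᵧ)). Under the
instrumental-variable assumptions (relevance, independence, exclusion
restriction) each Wald ratio β̂ⱼᵧ/β̂ⱼₓ estimates the same causal effect θ; the
estimators differ in how they combine the ratios and which violations they
tolerate.

**IVW.** θ̂ = Σ wⱼ β̂ⱼᵧ β̂ⱼₓ / Σ wⱼ β̂ⱼₓ², wⱼ = var(β̂ⱼᵧ)⁻¹ — first-order
weights that ignore exposure-side sampling error, equivalent to weighted
least squares through the origin. The fixed-effect standard error is
(Σ wⱼ β̂ⱼₓ²)^(−1/2); the default "multiplicative random-effects" model
inflates it by max(1, √(Q/(k−1))) with Q = Σ wⱼ (β̂ⱼᵧ − θ̂β̂ⱼₓ)² (Cochran),
so heterogeneity can widen but never narrow the interval.

**MR-Egger.** Instruments are oriented so that every β̂ⱼₓ ≥ 0, then β̂ⱼᵧ is
regressed on β̂ⱼₓ by WLS *with* an intercept. The slope is the causal
estimate (consistent under InSIDE even with directional pleiotropy); the
intercept estimates the average direct effect and its Wald test is the
pleiotropy diagnostic. Standard errors use the same max(1, residual scale)
clamp as IVW; a perfect fit falls back to the unit-scale covariance so the
intercept test remains defined.

**Weighted median.** Ratios are sorted; with standardized cumulative weights
sⱼ = (Σᵢ≤ⱼ wᵢ − wⱼ/2)/Σ wᵢ the estimate interpolates linearly to s = 0.5.
Consistent while valid instruments carry ≥ 50% of the weight. Standard error
by parametric bootstrap (β̂ⱼₓ*, β̂ⱼᵧ* drawn from their normal sampling
distributions; default 1000 replicates, seeded).

**Mode-based estimate.** The maximizer of a normal-kernel density of the
ratios with kernel weights ∝ β̂ⱼₓ²/var(β̂ⱼᵧ); bandwidth φ × 0.9·min(sd,
IQR/1.349)·k^(−1/5) (φ = 1 by default). The maximizer is located on a
512-point grid spanning the ratios ± 3 bandwidths and refined by bounded
scalar minimization; identical ratios short-circuit to the common value.
Bootstrap standard error as above.

**MR-Robust.** Huber M-regression (tuning 1.345, MAD scale) of β̂ⱼᵧ/seⱼᵧ on
β̂ⱼₓ/seⱼᵧ through the origin via statsmodels RLM (IRLS, max 200 iterations,
tolerance 1e-10). If the residual scale collapses to zero (exactly
proportional data) the exact weighted fit is returned directly.

**MR-RAPS.** Profile-score estimation using both sampling variances:
standardized residuals tⱼ(θ, τ²) = (β̂ⱼᵧ − θβ̂ⱼₓ)/√(var(β̂ⱼᵧ) +
θ²var(β̂ⱼₓ) + τ²), estimating equation Σ ψ(tⱼ) ∂tⱼ/∂θ = 0 with ψ the
identity (squared loss) or Huber clip at 1.345. With overdispersion on
(default), the systematic-pleiotropy variance τ² ≥ 0 solves
Σ[ψ(tⱼ)tⱼ − δ] = 0, δ = E[ψ(Z)Z] for Z ~ N(0,1) (δ = 2Φ(1.345) − 1 for the
Huber ψ). θ and τ² are solved alternately by bracketed root finding
(tolerance 1e-12); the standard error is the sandwich
√(Σψ(tⱼ)²(∂tⱼ/∂θ)²)/|dS/dθ|.

All confidence intervals are normal-theory θ̂ ± 1.96·se and all p-values
two-sided normal, keeping every method on a common reporting convention. For
binary outcomes the effects are log odds ratios per exposure SD; odds ratios
exp(θ̂) are produced only at reporting time.

**MR-PRESSO.** With leave-one-out IVW slopes θ̂₋ⱼ, the observed statistic is
RSS = Σ wⱼ(β̂ⱼᵧ − θ̂₋ⱼβ̂ⱼₓ)². Its null distribution comes from parametric
simulation (β̂ⱼₓ* ~ N(β̂ⱼₓ, seⱼₓ), β̂ⱼᵧ* ~ N(θ̂₋ⱼβ̂ⱼₓ, seⱼᵧ), default 1000
draws); the global p is the exceedance fraction. Per-instrument residual
contributions give two-sided simulation p-values, Bonferroni-adjusted over k
and flagged below 0.05; the corrected estimate is IVW after removal, and the
distortion test compares the induced shift with the shift from removing
random same-size subsets.

**Power (mRnd).** For a binary outcome with case proportion K and odds ratio
OR per exposure SD, b = K(OR/(1 + K(OR−1)) − 1), v = (K(1−K) − b²)/(N·R²ₓᵤ),
and power is the upper tail of a 1-df noncentral χ² with ncp = b²/v beyond
the central 1−α quantile; for continuous outcomes ncp = N·R²ₓᵤ·β². The OR is
interpreted per 1 SD of the exposure, the same scale on which the package
reports causal odds ratios.

## Instrument selection

Significance filtering is strictly p < 5×10⁻⁸ (a p exactly at the threshold
is excluded). Clumping is greedy: the remaining record with the smallest p
(ties broken by genomic order) becomes an index SNP and removes same-
chromosome records within 10,000 kb whose panel r² ≥ 0.01; r² is the squared
Pearson correlation of reference-panel dosages, and variants absent from the
panel are dropped rather than assumed independent. Per-SNP variance explained
uses 2p(1−p)β̂² when effect-allele frequencies are available (assuming
per-SD betas, i.e. unit trait variance), else t²/(t² + n − 2); the report
records which form was used.

## Harmonization

Variants are matched by chromosome and position; the exposure frame is
canonical and only outcome statistics are transformed. Non-palindromic
variants resolve to one of: identical labels (kept as-is), swapped labels
(β → −β, eaf → 1−eaf), or their strand complements. Palindromic variants are
aligned by frequency agreement only when both minor-allele frequencies are
below 0.42 (default); otherwise they are dropped as ambiguous. A `keep`
policy mimics a naive label-trusting merge and a `drop` policy discards all
palindromic variants; every non-direct action and every drop reason is
recorded per SNP.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with known truth:

* **Genotypes.** Haplotypes are thresholded latent Gaussians in AR(1) LD
  blocks. The latent correlation of each adjacent pair is calibrated by a
  tetrachoric inverse (bracketed root solve on the bivariate-normal orthant
  probability, evaluated via Owen's T) so the realized *dosage* correlation
  equals `ld_rho`. High LD between variants of very different MAFs is
  mathematically unattainable — as in real data — and is capped with a
  warning. With `ld_rho = 0`, dosages are drawn directly from Binomial(2, p).
* **Traits.** x = Σ γⱼgⱼ + e with Var(x) = 1; causal SNPs each explain
  h²ₓ/n_causal (equal-PVE effects, random signs — a deliberate
  simplification that keeps instrument strength uniform and selection
  stable). y = θx + Σ αⱼgⱼ + u with u ~ N(0,1). Balanced pleiotropy draws
  αⱼ ~ N(0, pleio_sd) on a fraction of causal SNPs; directional pleiotropy
  uses |N(0, pleio_sd)| signed like the exposure-increasing allele, so the
  contaminated Wald ratios shift coherently.
* **Summary statistics.** Exposure- and outcome-sample genotypes are drawn
  independently (an `overlap_fraction` option deliberately re-introduces
  sample overlap for robustness experiments). Per-SNP effects are marginal
  regressions, so standard errors scale as 1/√(2np(1−p)). Binary outcomes
  threshold the liability at its empirical 1−K quantile; log-odds effects
  use the logistic score approximation (exact per-SNP logistic fits behind
  `exact_logistic` for small panels).
* **Determinism.** A single seed; every stream (variants, panel, truth,
  exposure sample, outcome sample) derives from it by fixed tags, so the
  panel and the GWAS samples always agree on variants and MAFs.

What the generator does **not** model: realistic human LD maps, imputation
error, population stratification, relatedness, assortative mating, or
winner's curse. Passing recovery and calibration tests therefore validates
the estimators and pipeline plumbing under the stated sampling model, not
robustness to those additional real-data complications.

## Default study conditions

The generator defaults encode the package's reference study condition: 50
independent causal variants (MAF 0.10–0.40), h²ₓ = 3%, GWAS samples of
100,000, continuous outcome, θ = 0.5, no pleiotropy — strong instruments
(per-SNP F ≈ 60) so the selection pipeline retains essentially all of them.
The validation studies in `tests/test_acceptance.py` use:

* recovery: the defaults, θ ∈ {0, 0.5}, 100 seeds, median |θ̂ − θ| ≤ 0.02;
* calibration: m = 30, n = 20,000, h²ₓ = 7%, θ = 0, 1000 replicates —
  sizes chosen so a replicate is cheap while per-SNP instrument strength
  stays comparable (F ≈ 45); type-I error of the IVW z-test and the Egger
  intercept test within [0.03, 0.07] at nominal 0.05. The random-effects
  clamp makes IVW slightly conservative (≈ 0.04 expected), by design;
* pleiotropy robustness: 30% directional-pleiotropy instruments with
  pleio_sd = 0.02 (mean direct effect ≈ 40% of a γ), 200 seeds; weighted
  median and RAPS-Huber must beat IVW on |bias|;
* MR-PRESSO: a planted direct effect of 10 outcome standard errors among 21
  instruments (n = 50,000), flagged in ≥ 95/100 seeds; global-test size
  within [0.03, 0.07] over 500 null replicates.

## Numerical choices

* Bootstrap default 1000 replicates; all stochastic estimators are
  bit-reproducible given (inputs, seed, replicates).
* Huber tuning constant 1.345 for both MR-Robust and RAPS (≈ 95% Gaussian
  efficiency); configurable.
* RAPS brackets expand from the IVW estimate by ±max(4·se, 0.25), doubling
  up to 60 times before declaring failure; root tolerance 1e-12.
* MBE grid of 512 points over ratios ± 3 bandwidths, refined to 1e-12.
* p-values from χ² survival functions are floored at 1e-300.
* Clump tie-break for equal p-values: smaller (chromosome, position) first.
* Files are plain tab-delimited text with `NA` missing tokens; floats are
  serialized with shortest round-trip `repr`, so write → read is the exact
  identity and regenerated reports are byte-identical.

## Known limitations

* First-order IVW weights ignore var(β̂ⱼₓ); only RAPS models the
  exposure-side error. With weak instruments IVW inherits the usual
  weak-instrument bias (monitor the Cragg–Donald F).
* The binary-outcome score approximation deteriorates for large per-SNP
  effects or extreme case fractions; use `exact_logistic` there.
* Palindromic inference by frequency agreement can mis-orient variants with
  MAF near the 0.42 limit in small samples.
* No proxy-SNP lookup for instruments missing from the outcome GWAS, no
  multivariable MR, no liftover between genome builds, and rsid-based
  merging is intentionally absent (matching is by position).
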