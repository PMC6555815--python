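# Methods

This note records the models behind `polyscore`, the defaults that matter,
the numerical conventions, and what the synthetic generator does and does
not emulate.

## Scoring model

The polygenic score is the unnormalized weighted allele sum
`PRS_j = Σ_{i∈S, p_i<P_T} β̂_i x_ij` (no PLINK-style division by allele
count).  Conventions:

* **Inclusion rule.** Strict `p < P_T` at interior thresholds; the endpoint
  `P_T = 1.0` includes every harmonized SNP (`p ≤ 1`), so the full-inclusion
  score is well defined.
* **Missing dosages** are mean-imputed per variant (2 × counted-allele
  frequency from non-missing calls), both in scoring and in PCA.
* **Standardization** is cohort-wide (cases and controls pooled): z-scores
  center by the cohort mean and scale by the sample SD (ddof = 1).
* **Threshold selection** maximizes incremental Nagelkerke R² for the binary
  diagnosis over the grid {0.05, 0.1, 0.2, …, 1.0}; the selected threshold is
  reused for the severity analysis rather than re-optimized, avoiding a
  second selection step on the same data.

## Harmonization

Summary-statistic alleles are matched to the cohort by chromosome+position
(id matching available for position-free sources).  A variant is kept when
its allele pair matches the cohort's pair directly, after swapping (effect
sign flipped), or after strand complementation (with or without swap).
Strand-ambiguous A/T and C/G pairs are dropped by default because their
orientation cannot be inferred without frequency information; an override
flag exists.  All category counts (direct / swapped / strand / ambiguous /
mismatched / unmatched) are reported.

## QC

Filters run in a fixed, documented order — sample missingness (≤ 0.1) →
variant missingness (≤ 0.1) → MAF (≥ 0.01) → Hardy–Weinberg exact test
(P ≥ 0.001) — so counts in the report reconcile exactly.  The HWE test is
the conditional exact test (two-sided by probability mass, mid-p off),
enumerating heterozygote counts at fixed allele totals; this is the
convention of array-QC tooling and is validated against full rational
enumeration in the tests.

## LD operations

r² is the squared Pearson correlation of unphased allele counts (composite
LD), pairwise-complete over missing calls; pairs with fewer than 3 complete
observations or zero variance contribute r² = 0 inside window operations
and raise errors when queried directly.  Clumping is greedy: the smallest-P
unclaimed variant indexes a clump and claims unclaimed variants within
±250 kb at r² > 0.1; ties on P break to smaller position then lexicographic
id, making output deterministic.  Clumping uses the target cohort's own LD.
Pruning slides a 50-variant window in steps of 5, repeatedly breaking the
worst within-window pair above r² = 0.2 by removing the smaller-MAF member
(ties: later position), and passes repeat to a fixed point so the retained
set satisfies the pairwise constraint globally.

## Evaluation

* **Nagelkerke ΔR²**: logistic ML fits of null (intercept + covariates) and
  full (+ score); `R² = (1 − exp(2(ll₀ − ll)/n)) / (1 − exp(2 ll₀/n))` with
  ll₀ the intercept-only log-likelihood; the difference is reported with the
  Wald P of the score coefficient.  Separation is flagged as an error, never
  silently estimated; a BFGS retry guards against fragile Newton steps.
* **Quantile contrasts**: samples are ranked by (score, sample id) — a
  stable, deterministic tie-break — into q groups whose sizes differ by at
  most one (remainders to the lower quantiles); the outcome is regressed on
  quantile indicators with the lowest quantile as reference; Wald 95% CIs,
  exponentiated for odds ratios.
* **Severity** is analyzed over the full cohort (cases + controls); the
  evaluation helpers accept any subset, so a cases-only analysis is a slice
  away.
* **PCA covariates** (default k = 5) are computed on the LD-pruned,
  column-standardized dosage matrix; component signs follow the
  largest-magnitude-loading-positive convention so results are reproducible
  across BLAS implementations.
* **Wilcoxon rank-sum** uses the exact null distribution when both groups
  have ≤ 25 observations and the pooled sample is tie-free; otherwise the
  tie-corrected normal approximation without continuity correction.  (Full
  enumeration with ties is combinatorially infeasible at that size; the
  exact no-ties distribution plus tie-corrected approximation covers both
  regimes.)

## Ancestry

IBS similarity is the mean over shared non-missing variants of
`1 − |x_j − x_k|/2`.  Clusters come from unconstrained average-linkage
agglomeration on `1 − IBS`, cut at k (default 4), labels ordered by
decreasing cluster size.  This deliberately approximates the
restricted-complete-linkage behavior of the original genotype-analysis
tool: clusters are used only to partition samples for stratified
evaluation, so label recovery — validated on Balding–Nichols simulations
(adjusted Rand ≥ 0.95 at Fst 0.1) — is the relevant property, not
bit-compatibility.

## Liability-threshold theory

`max_auc`/`auc_given_variance_explained` use the normal approximation to
the score distribution in cases and controls (group means `r²·i`, variances
`r²(1 − r²·i(i−T))`).  At h² = 0.30, K = 0.08 the closed form gives 0.8039;
exact 2-D integration gives 0.8036 and a 10⁷-draw Monte-Carlo simulation
agrees within 0.005, which the tests assert.  The finite-sample projection
`r² = h²·Nh²/(Nh² + M)` is the classical expected-accuracy form for N
training samples and M unlinked non-null markers, validated against a
two-stage discovery/test simulation (10% relative at M = 1000).  It assumes
training and evaluation samples are random population draws — not
case-enriched — and unlinked markers with no thresholding, so it is an
upper envelope for a C+T pipeline on LD-structured data (see below).

Power uses the additive-penetrance GRR model `f₁ = λf₀, f₂ = (2λ−1)f₀`
with prevalence fixing `f₀`, HWE genotype frequencies conditioned on
case/control status, and a noncentral chi-square approximation to the 1-df
trend test with NCP `(μ₁−μ₀)²/(v₁/n₁ + v₀/n₀)`; `detectable_grr` bisects
the monotone power curve to 10⁻⁴.  Monte-Carlo cross-checks at relaxed α
agree within 0.02 absolute.

## Synthetic-study generator

The generator reproduces the statistical structure the analysis assumes:

* **Frequencies**: ancestral ~ U(0.05, 0.95); diverged populations follow
  the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F).
* **Genotypes**: two haplotypes per individual, each a blockwise AR(1)
  Gaussian copula (default latent lag-1 correlation 0.8, blocks of 20
  variants at 5 kb spacing) thresholded at each variant's frequency
  quantile.  This yields realistic within-block LD (adjacent genotype
  r² ≈ 0.4) with exact frequency control and no cross-block correlation;
  it does not model recombination-map hotspots, allele-age–frequency
  correlation, or long-range LD.
* **Architecture**: a uniform random sparse causal set; standardized
  effects are normal, rescaled so their squares sum to h² exactly.
  Per-allele effects are fixed from *ancestral* frequencies, so the same
  allelic effect applies in every derived population; liability is centered
  within each cohort (prevalence stays K everywhere) while the variance
  drift across populations — one driver of cross-ancestry attenuation — is
  retained.  Attenuation from genuinely different LD maps is only partially
  emulated (diverged populations share the copula block structure), so the
  generator understates the attenuation seen in real trans-ancestry data.
* **Phenotypes**: liability = genetic value + N(0, 1−h²); case above
  `Φ⁻¹(1−K)`.  Severity maps each group's conditional liability quantile
  monotonically onto a clinician-like 0–120 scale (cases → [37, 102],
  median 65.5; controls → [0, 24], median 2; power-law exponents solve the
  median constraints exactly), plus N(0, 2) measurement noise, truncated to
  [0, 120].  The gap between group ranges mirrors cohorts that exclude
  intermediate-severity participants.  The noise share is a free
  configuration parameter; nothing in the tests asserts a particular
  severity R².
* **Discovery GWAS**: per-variant univariate logistic regression
  (vectorized Newton, float32 elementwise with float64 accumulation),
  Wald P values; no covariates, because the discovery population is a
  single homogeneous cohort by construction.
* **Target**: cases oversampled without replacement to a requested fraction
  (default 0.5), emulating case-control ascertainment.

Default conditions (`SimConfig()`): m = 5,000 markers, 500 causal,
h² = 0.30, K = 0.08, 20,000 discovery samples, 1,000-sample 50/50 target —
a deliberate scale-down of a realistic design (tens of thousands of
discovery samples, ~50,000 non-null markers) that keeps a full study run
near half a minute on one core.  The test suite runs the recovery analysis
at these defaults across 10 seeds and the cross-ancestry comparison at a
further reduced scale (m = 2,000, 5,000 discovery samples) across 20 seeds.

**What passing tests show, and don't.**  Parameter recovery (observed
incremental R² within a factor of two of the theoretical projection, in the
median across seeds) demonstrates internal consistency between the
generator, the pipeline, and the theory — not real-data performance.  On
real cohorts, imputation error, phenotype heterogeneity, discovery/target
trait mismatch, and stronger ancestry/LD differences all push observed R²
further below the projection.  The C+T pipeline itself sits measurably
below the projection even in simulation (median ratio ≈ 0.6 at the default
conditions) because thresholding discards weak causal signal and null SNPs
add noise — the projection assumes an oracle that scores every non-null
marker and nothing else.

## Numerical and degenerate-input conventions

* Dosage matrices are floats with NaN as missing; validation rejects
  non-{0,1,2} entries naming the offending cell.
* Empty-after-QC cohorts, zero harmonization overlap, empty effective SNP
  sets, single-class outcomes, constant outcomes, and separation all raise
  typed errors naming the condition; nothing degrades to a silent estimate.
* All generators and the pipeline are bit-reproducible given (config,
  seed); seeds are split with `numpy` SeedSequence spawning so adding a
  stage never perturbs earlier streams.
* Reported P values are clipped to ≥ 1e-300 so downstream (0, 1]
  validation holds at extreme z-statistics.

## Known limitations

* No phasing/imputation; VCF ingestion and genome-build liftover are out of
  scope (inputs are PLINK 1 binary or transparent text dosages).
* Clumping uses target-cohort LD; external reference-panel clumping is not
  implemented.
* No shrinkage/Bayesian PRS weighting; C+T only.
* The theory module's projections assume random population sampling;
  ascertainment-corrected projections are not provided.
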