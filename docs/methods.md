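# Methods

`mesorisk` implements an integrated genetic + epigenetic risk-score analysis
for pleural mesothelioma (PM), an asbestos-driven cancer in which only a
fraction of exposed individuals develop disease. The pipeline covers the full
path from a per-variant association scan to combined risk-model evaluation,
and ships a synthetic-cohort generator so every stage is testable without
access to individual-level human data.

## The disease model the generator emulates

Case status is drawn from a logistic model

    logit P(Y = 1) = alpha + sum_m beta_m g_m + gamma_low 1{E=1} + gamma_high 1{E=2}
                     + sum_k delta_k g_k 1{E=e_k} + a (age - age_mean) + s 1{male}

with dosages `g` in {0,1,2}, a three-level occupational asbestos-exposure
variable `E` (0 none, 1 low, 2 high), and optional gene-by-exposure product
terms. Methylation beta-values are Beta-distributed per CpG,
`Beta(mu * phi, (1-mu) * phi)`, with causal CpGs shifted by `delta` on the
mean in cases (clipped into (0.001, 0.999) to preserve the [0,1] support).

### LD structure

Haplotypes within a block are latent AR(1) Gaussians thresholded at the
allele-frequency quantile; the dosage is the sum of two independent
haplotypes, so variants sit in Hardy–Weinberg proportions. Thresholding
attenuates correlation (a latent 0.9 yields genotype correlation ≈ 0.70), so
the latent adjacent correlation is **calibrated** through the exact
bivariate-normal orthant probability so that the realized genotype
correlation of adjacent variants equals the requested `ld_rho`. When the two
variants have unequal allele frequencies the attainable correlation is
bounded below 1 (exactly as for real genotypes); the calibration then caps at
the attainable maximum. Across blocks variants are independent. An optional
two-subpopulation mode perturbs per-variant allele frequencies under a
Balding–Nichols Beta model with a chosen fixation index; it is off by default
(no published anchor for the magnitude of the within-study ancestry
divergence), and PCA tests switch it on explicitly.

### Default study conditions

The default `RunConfig` mirrors the retrospective case–control design this
package emulates, with sizes chosen for desk-scale simulation:

| knob | default | rationale |
|---|---|---|
| cases / controls | 387 / 362 | the retrospective design's post-QC counts |
| population size | 4000 | large enough to sample the design at ~20% prevalence |
| variants | 60 blocks × 25 (1500), `ld_rho` 0.6 | enough blocks for clumping to matter |
| causal variants | 20, log-OR ±0.6 alternating | per-allele effect on the scale of the study's top hits (meta ORs 0.36–0.45 ⇒ \|log-OR\| ≈ 0.8–1.0) |
| exposure log-ORs | 1.8 (low), 2.4 (high) | crude ORs recoverable from the cohort's exposure margins |
| exposure distribution | (0.30, 0.42, 0.28) | control-like margins |
| missing exposure | 6.5%, cases only | the design's missing exposure histories appear only among retrospective cases |
| age / sex | N(65, 11²) years, 71% male, age log-OR 0.04/yr | cohort demographics |
| CpGs | 2000, 30 causal, `delta` ±0.12 (25 hypo / 5 hyper) | mirrors the reported 58:10 hypo:hyper imbalance; effect sizes just above the 0.10 selection filter |
| Beta precision `phi` | 50 | per-CpG SD ≈ 0.05–0.07, typical of variable blood-array probes |

Every operation takes an explicit integer seed; the pipeline derives
per-stage seeds by fixed offsets from the run seed, so a (config, seed) pair
reproduces a run byte-for-byte.

### What the generator does not emulate

Real array data have correlated neighbouring CpGs, batch/chip structure
richer than the single categorical batch label simulated here, genotyping and
imputation error, and cryptic relatedness/ancestry gradients rather than
clean two-cluster structure. Passing tests therefore demonstrate the
*statistical machinery* (estimators, selection rules, test calibration), not
that real-data effect sizes of the reported magnitude are recoverable.
Because the synthetic causal CpGs are independent with uniform effects just
above the selection filter, the simulated methylation score separates cases
nearly perfectly — stronger than any real methylation score; the qualitative
claim checked is the *ordering* (methylation adds discrimination over the
base model; combined models are not dominated), not the absolute AUC.

## Analysis layer

**Sample QC.** Kinship is half the standardized-genotype relationship
matrix, `Phi_ij = (1/2M) sum_m (g_im - 2f_m)(g_jm - 2f_m) / (2 f_m (1-f_m))`
(duplicates ≈ 0.5, first degree ≈ 0.25); one member of each pair above 0.125
is removed (lower call rate, ties to the lexicographically later id).
Heterozygosity outliers beyond 3 SD are flagged, and PCA outliers are removed
iteratively with PCs recomputed each round.

**Association scan.** One covariate-adjusted logistic regression per variant
(`status ~ dose + covariates`, exposure as two indicators vs none), fit by
Newton/IRLS batched across variants (shared response and covariate block;
stacked per-variant Hessians solved in one call; a 1e-12-scaled ridge keeps
near-separated fits solvable and a flag marks non-convergence or
|coefficient| > 15). Gradient tolerance 1e-8, 50 iterations. Wald tests;
variants below MAF 0.01 or MAC 20 are excluded and counted. The scan is
cross-checked against statsmodels coefficient-for-coefficient in tests.
Genomic inflation is the median association chi-square over 0.4549.

**Meta-analysis.** Fixed-effect inverse variance with Cochran's Q, Higgins'
I² = max(0, (Q - df)/Q)·100 and a chi-square heterogeneity p; alleles are
harmonized to the first study (swapped coding flips the sign; incompatible
pairs are dropped and counted); single-study variants pass through flagged.

**PRS.** Greedy LD clumping (index = lowest p; removes r² ≥ 0.1 within
±250 kb; ties by position), clump r² computed on the analysis genotypes
themselves. The weight grid runs over inclusion thresholds 5e-8 … 1e-3
(six points; the stated endpoints plus intermediate decades); for each
threshold the clumped sub-threshold training variants carry their training
log-ORs as weights, and the best model is the one with the highest raw-score
test-set AUC, with the two-sample K–S p as tie-breaker, then the smaller
threshold. Raw-score (not covariate-adjusted) AUC is used for selection; the
alternative is a configuration flag. Missing dosages are imputed at twice
the target allele frequency inside scoring. Cross-dataset transport uses a
PCA-based normalization: reference scores are regressed on reference PCs and
the target score is the residual from that fit, standardized by the
reference residual moments.

**MRS.** Per-CpG linear regression of beta-values on status and covariates
(beta-values analysed directly, no M-transform; white-cell composition
deliberately not adjusted, matching the design choice of the study this
emulates). All CpGs share one design, so the scan is a single least-squares
solve. Selection requires |effect| strictly greater than 0.10 **and**
BH-FDR q < 0.05; the effect estimate is the weight (unit ± weights behind a
flag). Scores are z-standardized within dataset. Quantile normalization maps
every sample onto the mean order statistics, ties sharing the mean of their
slots.

**Evaluation.** Logistic risk models over {age, sex, exposure, PRS, MRS,
PRS×MRS}; McFadden and Nagelkerke pseudo-R² are both reported (sources
rarely say which they used). AUCs carry DeLong variances; model comparisons
use the paired DeLong test on the structural components. Percentile ORs
threshold the combined evaluation sample's score distribution (controls-only
reference behind a flag) and come from a covariate-adjusted logistic model
with Wald CIs on the log scale (profile CIs would be asymmetric; Wald is the
oracle-testable default). Categorical NRI uses the (0.20, 0.80) probability
cuts, the case component P(up)−P(down), the control component
P(down)−P(up), and the standard two-proportion z. The combined tercile rule
calls a sample high-risk only when *both* scores sit in their top tercile
(the natural reading of "based on the percentiles of both scores";
either-high is available behind a flag).

**Interaction.** Multiplicative-scale product-term Wald tests
(exposure any-vs-none by default, three-level behind a flag); per-stratum
carrier 2×2 ORs with Woolf CIs (covariate-adjusted logistic per stratum when
covariates are given); RERI = OR11 − OR10 − OR01 + 1 from a logistic fit with
binary carrier and exposure indicators, delta-method CI from the coefficient
covariance (gradient (OR11−OR10, OR11−OR01, OR11)), with a bootstrap
percentile fallback under separation. RERI covariates default to age + sex.

## Numerical and design notes

* Coordinates are 1-based everywhere (VCF convention); TSV/UTF-8 text
  formats with 'NA' for missing.
* Exposure enters all models as two dummies vs none; rows with missing
  exposure are dropped with a logged count (an explicit missing category is
  a configuration choice left to the caller).
* MAF is computed on the combined analysis sample (cases + controls).
* Wilcoxon tests enumerate the exact rank-sum distribution when
  n₁+n₂ ≤ 12 (tail-doubled two-sided p), otherwise use the tie-corrected
  normal approximation.
* Null calibration of the end-to-end pipeline is asserted on the raw
  out-of-sample score AUC; the in-sample fitted-model AUC carries the usual
  optimism bias (≈0.55 with five noise predictors at n≈375) and is reported
  but not used as the calibration quantity.
* The two-sample K–S p-value is the asymptotic Kolmogorov form with
  effective n = n₁n₂/(n₁+n₂); it tracks the exact permutation p closely in
  the tails (where decisions happen) and less closely mid-range at n ≈ 50.
* The greedy age-ascending matcher of the nested design is a maximal
  matching, guaranteed within a factor two of the optimum; tests verify the
  bound by enumeration on small instances.
* Simulation sizes in the test suite (e.g. 1000 replicates at n = 2000 for
  CI coverage, 200 null scans of 500 variants for calibration, 20 seeded
  end-to-end runs) were chosen as the smallest sizes at which the binomial
  slack of each assertion is decisive.

## Known limitations

* No mixed-model or saddlepoint machinery: the scan is plain covariate-
  adjusted logistic regression, appropriate for unrelated post-QC samples.
* No genotype imputation, X-chromosome handling, array preprocessing,
  cell-type deconvolution, annotation or pathway tooling.
* Percentile-OR CIs are Wald; heavily separated cells report unbounded CIs
  rather than profile intervals.
* The NRI significance test uses the simple asymptotic two-proportion
  variance.
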