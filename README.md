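# mesorisk

Integrated **polygenic (PRS)** and **methylation (MRS) risk-score** modelling
for pleural mesothelioma — a rare, aggressive cancer caused by asbestos
exposure in which only a fraction of exposed individuals develop disease.
The package is aimed at molecular epidemiologists who want a tested,
reproducible implementation of the full analysis path:

1. **synthetic cohorts** with block-LD genotypes, Beta-distributed
   methylation, a three-level occupational asbestos-exposure variable, and a
   logistic disease model (retrospective case–control and 1:1
   age/sex/exposure-matched nested designs);
2. **sample QC** (kinship, heterozygosity, iterative-PCA outliers),
   covariate-adjusted **logistic association scan** with genomic inflation
   λ, and fixed-effect inverse-variance **meta-analysis** (Cochran's Q,
   Higgins' I²);
3. **PRS** by LD clumping (r² < 0.1 within 250 kb) and p-value thresholding
   (5×10⁻⁸ … 10⁻³), selected by test-set AUC with a Kolmogorov–Smirnov
   tie-break, plus PCA-based cross-dataset score normalization;
4. **MRS** from differential methylation on β-values (effect size > |0.10|,
   FDR q < 0.05), weighted by the regression effects;
5. **risk-model evaluation**: AUC with DeLong variance and paired DeLong
   model comparison, percentile-threshold odds ratios, sensitivity /
   specificity, categorical net reclassification improvement (NRI),
   Fisher / Wilcoxon / K–S tests, pseudo-R², combined tercile risk groups;
6. **gene-by-exposure interaction**: product-term tests, stratified ORs and
   additive-scale interaction via RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 with a
   delta-method CI.

The scores are weighted sums, `score_i = Σ_m w_m x_im`, with weights from
association log-ORs (PRS, per alt-allele dose after harmonization) or
differential-methylation effects (MRS, per β-value), z-standardized within
the evaluation dataset. See `docs/methods.md` for the model, defaults and
numerical choices.

## Worked example

```python
from mesorisk import RunConfig, run_full

report = run_full(RunConfig(seed=1))
for k in ("auc_base", "auc_prs", "auc_mrs", "auc_combined",
          "or_prs_p80", "or_prs_p90", "or_prs_p95",
          "nri_overall", "nri_cases", "nri_controls", "genomic_lambda"):
    print(f"{k:16s} {report[k]:.4f}")
```

prints (seed 1, default study conditions):

```
auc_base         0.7177
auc_prs          0.7431
auc_mrs          1.0000
auc_combined     1.0000
or_prs_p80       2.5041
or_prs_p90       4.1033
or_prs_p95       5.2420
nri_overall      1.7671
nri_cases        0.9615
nri_controls     0.8056
genomic_lambda   1.4192
```

Reading: the base model (age, sex, exposure) discriminates at AUC 0.72;
adding the PRS lifts it to 0.74, and the odds of disease for individuals
above the 80th/90th/95th PRS percentile rise monotonically (OR 2.5 → 4.1 →
5.2) — the qualitative risk gradient the method is designed to expose. The
synthetic methylation score separates cases essentially perfectly under the
default generating conditions (30 independent causal CpGs), so the combined
model inherits AUC ≈ 1; the NRI decomposes exactly into its case and control
components. The effect-rich λ is above 1 because a third of the simulated
genome carries true signal; under null conditions λ ≈ 1.01.

The same run is available from the shell:

```bash
mesorisk run --out-dir out/ --seed 1          # report.tsv + run.log
mesorisk simulate --out-dir sim/ --seed 3     # VCF + methylation/cohort TSVs
mesorisk assoc --vcf sim/genotypes.vcf --cohort sim/cohort.tsv \
    --covar age,sex,exposure --pcs 3 --out stats.tsv
```

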