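"""End-to-end orchestration: simulate a cohort, QC, scan, build PRS and MRS,
and evaluate the combined risk models, all reproducible from (config, seed).

The default configuration mirrors the study conditions of the retrospective
design this package emulates: 387 cases / 362 controls sampled from a larger
population, a three-level asbestos-exposure variable with strong main
effects, 50:50 stratified train/test split, clump-and-threshold PRS on the
training association scan, and an effect-size/FDR-filtered MRS from the
training differential-methylation scan.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, interact, mrs as mrs_mod, prs as prs_mod, riskeval, synth
from .containers import MesoriskError, PopulationSample

logger = logging.getLogger("mesorisk")


@dataclass
class RunConfig:
    """All knobs of a seeded end-to-end run."""

    seed: int = 0
    design: str = "retrospective"  # or "matched_nested"

    # population / genotypes
    n_population: int = 4000
    n_blocks: int = 60
    variants_per_block: int = 25
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_spacing_bp: int = 5_000

    # generating effects
    n_causal_variants: int = 20
    causal_log_or: float = 0.6  # alternating sign across causal variants
    exposure_log_ors: tuple[float, float] = (1.8, 2.4)
    exposure_probs: tuple[float, float, float] = (0.30, 0.42, 0.28)
    baseline_logit: float = -2.8
    age_log_or: float = 0.04
    sex_log_or: float = 0.05
    exposure_missing_fraction: float = 0.065

    # methylation
    n_cpgs: int = 2000
    n_causal_cpgs: int = 30
    cpg_delta: float = 0.12  # 5/6 hypomethylated in cases, 1/6 hypermethylated
    beta_precision: float = 50.0

    # sampling design
    n_cases: int = 387
    n_controls: int = 362
    age_caliper: float = 1.5

    # analysis
    run_qc: bool = True
    n_pcs: int = 3
    split_fraction: float = 0.5
    thresholds: tuple[float, ...] = prs_mod.DEFAULT_THRESHOLD_GRID
    clump_r2_max: float = 0.1
    clump_window_bp: int = 250_000
    maf_min: float = 0.01
    mac_min: int = 20
    dm_min_abs_effect: float = 0.10
    dm_max_q: float = 0.05
    percentiles: tuple[float, ...] = (80, 90, 95)
    nri_cuts: tuple[float, float] = (0.20, 0.80)
    assoc_covariates: tuple[str, ...] = ("age", "sex", "exposure")
    dm_covariates: tuple[str, ...] = ("age", "sex", "exposure", "batch", "PC1", "PC2")
    base_model: tuple[str, ...] = ("age", "sex", "exposure")
    run_interaction: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise MesoriskError("split_fraction must lie in (0, 1)")
        if self.design not in ("retrospective", "matched_nested"):
            raise MesoriskError(f"unknown design {self.design!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MesoriskError(f"unknown config keys: {sorted(unknown)}")
        for key in (
            "maf_range", "exposure_log_ors", "exposure_probs", "thresholds",
            "percentiles", "nri_cuts", "assoc_covariates", "dm_covariates", "base_model",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def null(self) -> "RunConfig":
        """Copy with every generating effect zeroed (calibration runs)."""
        return dataclasses.replace(
            self,
            n_causal_variants=0,
            causal_log_or=0.0,
            exposure_log_ors=(0.0, 0.0),
            n_causal_cpgs=0,
            cpg_delta=0.0,
            age_log_or=0.0,
            sex_log_or=0.0,
            baseline_logit=0.0,  # balanced prevalence so both strata stay samplable
        )


def split_train_test(
    cohort: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Status-stratified random split; per-status training counts are
    floor(n * fraction), so they differ from the exact fraction by < 1."""
    if not (0.0 < fraction < 1.0):
        raise MesoriskError("split fraction must lie strictly inside (0, 1)")
    status = cohort["status"]
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for g in (1, 0):
        ids = list(cohort.index[status == g])
        if len(ids) < 2:
            raise MesoriskError(f"need >= 2 samples with status {g} to split")
        perm = rng.permutation(len(ids))
        k = int(np.floor(len(ids) * fraction))
        train.extend(ids[i] for i in perm[:k])
        test.extend(ids[i] for i in perm[k:])
    return sorted(train), sorted(test)


def _simulate_population(config: RunConfig) -> PopulationSample:
    blocks = []
    for b in range(config.n_blocks):
        chrom = str(b % 22 + 1)
        blocks.append(
            synth.VariantBlockSpec(
                n_variants=config.variants_per_block,
                maf_low=config.maf_range[0],
                maf_high=config.maf_range[1],
                ld_rho=config.ld_rho,
                chromosome=chrom,
                start_pos=1 + (b // 22) * 2_000_000,
                spacing=config.block_spacing_bp,
            )
        )
    genotypes = synth.simulate_genotypes(config.n_population, blocks, seed=config.seed + 11)
    vids = genotypes.variant_ids
    causal: dict[str, float] = {}
    step = max(1, len(vids) // max(1, config.n_causal_variants))
    for k in range(config.n_causal_variants):
        sign = 1.0 if k % 2 == 0 else -1.0
        causal[vids[(k * step) % len(vids)]] = sign * config.causal_log_or
    causal_cpgs: dict[str, float] = {}
    for k in range(config.n_causal_cpgs):
        sign = -1.0 if k % 6 < 5 else 1.0  # mostly hypomethylated in cases
        causal_cpgs[f"cg{k:06d}"] = sign * config.cpg_delta
    effects = synth.EffectSpec(
        causal_variants=causal,
        causal_cpgs=causal_cpgs,
        exposure_log_ors=config.exposure_log_ors,
        baseline_logit=config.baseline_logit,
        age_log_or=config.age_log_or,
        sex_log_or=config.sex_log_or,
    )
    cohort = synth.simulate_phenotype(
        genotypes,
        effects,
        exposure_probs=config.exposure_probs,
        exposure_missing_fraction=config.exposure_missing_fraction,
        seed=config.seed + 23,
    )
    population = PopulationSample(genotypes=genotypes, cohort=cohort)
    if config.design == "retrospective":
        sample = synth.sample_case_control(
            population, config.n_cases, config.n_controls, seed=config.seed + 37
        )
    else:
        sample = synth.sample_matched_nested(
            population, age_caliper=config.age_caliper, seed=config.seed + 37
        )
    rng = np.random.default_rng(config.seed + 41)
    cohort = sample.cohort.copy()
    cohort["batch"] = rng.integers(0, 2, size=len(cohort))
    margin = min(0.45, abs(config.cpg_delta) + 0.03)
    meth = synth.simulate_methylation(
        cohort,
        n_cpgs=config.n_cpgs,
        causal_cpgs=causal_cpgs,
        precision=config.beta_precision,
        seed=config.seed + 53,
        baseline_mean_range=(margin, 1.0 - margin),
    )
    return PopulationSample(
        genotypes=sample.genotypes, cohort=cohort, methylation=meth, pairs=sample.pairs
    )


def run_full(config: RunConfig, out_dir=None) -> dict:
    """Execute simulate -> QC -> scan -> PRS -> DM -> MRS -> evaluate.

    Returns a flat report dict of named metrics; with ``out_dir`` the report
    is also written as a diff-able TSV plus a plain-text log.  Any stage
    failure aborts with the stage name attached.
    """
    report: dict[str, float | int | str] = {"seed": config.seed, "design": config.design}
    stage = "simulate"
    try:
        sample = _simulate_population(config)
        report["n_samples"] = sample.n_samples
        report["n_cases"] = int(sample.cohort["status"].sum())
        report["n_controls"] = int((1 - sample.cohort["status"]).sum())

        if config.run_qc:
            stage = "qc"
            qc = assoc.qc_samples(sample.genotypes)
            report["n_qc_removed"] = sample.n_samples - len(qc.kept_samples)
            keep_pos = [i for i, s in enumerate(sample.sample_ids) if s in set(qc.kept_samples)]
            sample = sample.subset(np.array(keep_pos))

        stage = "pca"
        pcs = assoc.compute_pcs(sample.genotypes, config.n_pcs)
        cohort = sample.cohort.join(pcs)

        stage = "split"
        train_ids, test_ids = split_train_test(
            cohort, fraction=config.split_fraction, seed=config.seed + 61
        )
        assert not set(train_ids) & set(test_ids)
        train = sample.subset_ids(train_ids)
        test = sample.subset_ids(test_ids)
        train_cohort = cohort.loc[train_ids]
        test_cohort = cohort.loc[test_ids]
        report["n_train"] = len(train_ids)
        report["n_test"] = len(test_ids)

        stage = "assoc_scan"
        covs = list(config.assoc_covariates) + [f"PC{i+1}" for i in range(config.n_pcs)]
        scan = assoc.assoc_scan(
            train.genotypes,
            train_cohort,
            covariate_names=covs,
            maf_min=config.maf_min,
            mac_min=config.mac_min,
        )
        report["n_variants_tested"] = len(scan.table)
        report["genomic_lambda"] = assoc.genomic_lambda(scan.table["p_value"])

        stage = "prs"
        thr = prs_mod.threshold_scan(
            scan.table,
            train.genotypes,
            test.genotypes,
            test_cohort,
            thresholds=config.thresholds,
            r2_max=config.clump_r2_max,
            window_bp=config.clump_window_bp,
        )
        report["prs_threshold"] = thr.best_threshold
        report["prs_n_variants"] = thr.best_weights.n_variants
        prs_raw = prs_mod.score(test.genotypes, thr.best_weights).scores
        prs_z = (prs_raw - prs_raw.mean()) / prs_raw.std(ddof=1)

        stage = "dm"
        dm = mrs_mod.dm_scan(
            train.methylation, train_cohort, covariate_names=list(config.dm_covariates)
        )
        sel, counts = mrs_mod.select_cpgs(
            dm, min_abs_effect=config.dm_min_abs_effect, max_q=config.dm_max_q
        )
        report["mrs_n_cpgs"] = counts["n_selected"]
        report["mrs_n_hypo"] = counts["n_hypo"]
        report["mrs_n_hyper"] = counts["n_hyper"]

        stage = "mrs"
        mrs_z = mrs_mod.mrs_score(test.methylation, sel).scores

        stage = "evaluate"
        status = test_cohort["status"].to_numpy(dtype=int)
        models = {
            "base": riskeval.fit_risk_model(test_cohort, list(config.base_model)),
            "prs": riskeval.fit_risk_model(
                test_cohort, list(config.base_model) + ["PRS"], prs=prs_z
            ),
            "mrs": riskeval.fit_risk_model(
                test_cohort, list(config.base_model) + ["MRS"], mrs=mrs_z
            ),
            "combined": riskeval.fit_risk_model(
                test_cohort, list(config.base_model) + ["PRS", "MRS"], prs=prs_z, mrs=mrs_z
            ),
            "interaction": riskeval.fit_risk_model(
                test_cohort,
                list(config.base_model) + ["PRS", "MRS", "PRSxMRS"],
                prs=prs_z,
                mrs=mrs_z,
            ),
        }
        eval_ids = models["base"].fitted.index  # rows kept after exposure drop
        y_eval = test_cohort.loc[eval_ids, "status"].to_numpy(dtype=int)
        for name, fit in models.items():
            report[f"auc_{name}"] = fit.auc
            report[f"auc_{name}_ci_low"], report[f"auc_{name}_ci_high"] = fit.auc_ci
            report[f"r2_mcfadden_{name}"] = fit.mcfadden
            report[f"r2_nagelkerke_{name}"] = fit.nagelkerke
        for name in ("prs", "mrs", "combined", "interaction"):
            _, z, p = riskeval.delong_compare(
                models[name].fitted.loc[eval_ids], models["base"].fitted.loc[eval_ids], y_eval
            )
            report[f"delong_p_{name}_vs_base"] = p
        nri = riskeval.nri_categorical(
            models["base"].fitted.loc[eval_ids],
            models["combined"].fitted.loc[eval_ids],
            y_eval,
            cut_points=config.nri_cuts,
        )
        report["nri_overall"] = nri.overall
        report["nri_cases"] = nri.case_component
        report["nri_controls"] = nri.control_component
        report["nri_p"] = nri.p

        for label, sc in (("prs", prs_z), ("mrs", mrs_z)):
            # raw out-of-sample score discrimination (no model fitting)
            a, _, ci = riskeval.auc_delong(sc.loc[test_cohort.index], status)
            report[f"auc_{label}_score"] = a
            report[f"auc_{label}_score_ci_low"], report[f"auc_{label}_score_ci_high"] = ci
            ks_d, ks_p = riskeval.ks_two_sample(
                sc.loc[test_cohort.index[status == 1]],
                sc.loc[test_cohort.index[status == 0]],
            )
            report[f"ks_p_{label}"] = ks_p
            for row in riskeval.percentile_or(
                sc, test_cohort, covariate_names=list(config.base_model),
                percentiles=config.percentiles,
            ):
                pc = int(row.percentile)
                report[f"or_{label}_p{pc}"] = row.or_estimate
                report[f"or_{label}_p{pc}_ci_low"] = row.ci_low
                report[f"or_{label}_p{pc}_ci_high"] = row.ci_high
            sens, spec = riskeval.sens_spec_at(
                sc.loc[test_cohort.index], status, percentile=80
            )
            report[f"sens_{label}_p80"] = sens
            report[f"spec_{label}_p80"] = spec

        if config.run_interaction:
            stage = "interaction"
            top = scan.table.loc[scan.table["converged"]].nsmallest(1, "p_value")
            if len(top):
                vid = top["variant_id"].iloc[0]
                dose = pd.Series(
                    test.genotypes.dosages[:, test.genotypes.variant_ids.get_loc(vid)],
                    index=test_cohort.index,
                )
                expo = pd.to_numeric(test_cohort["exposure"], errors="coerce")
                keep = expo.notna()
                rr = interact.reri(
                    test_cohort.loc[keep],
                    (dose[keep] >= 1).astype(float),
                    (expo[keep] > 0).astype(float),
                    covariate_names=["age", "sex"],
                )
                report["reri_top_variant"] = rr.reri
                report["reri_ci_low"], report["reri_ci_high"] = rr.ci_low, rr.ci_high
                report["reri_classification"] = rr.classification
    except MesoriskError as err:
        raise MesoriskError(f"stage {stage!r} failed: {err}") from err

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        rows = [(k, _fmt(v)) for k, v in report.items()]
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            os.path.join(out_dir, "report.tsv"), sep="\t", index=False
        )
        with open(os.path.join(out_dir, "run.log"), "w", encoding="utf-8") as fh:
            fh.write(f"mesorisk run (seed={config.seed}, design={config.design})\n")
            for k, v in report.items():
                fh.write(f"  {k} = {_fmt(v)}\n")
    return report


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)
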