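"""Polygenic risk scores: weight harmonization, LD clumping, weighted-sum
scoring, p-value-threshold model selection, and PCA-based cross-dataset
score normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MesoriskError, RiskScoreSet, validate_cohort
from .riskeval import auc_delong, ks_two_sample

logger = logging.getLogger("mesorisk")

#: Inclusion thresholds for the p-value grid (endpoints 5e-8 and 1e-3).
DEFAULT_THRESHOLD_GRID = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class WeightSet:
    """Per-feature weights (variants or CpGs) defining a risk score."""

    entries: pd.DataFrame  # variant_id/cpg_id index; effect_allele, other_allele, weight
    source_threshold: float | None = None
    kind: str = "variant"

    def __post_init__(self) -> None:
        if "weight" not in self.entries.columns:
            raise MesoriskError("weight set needs a 'weight' column")
        if self.entries.index.has_duplicates:
            raise MesoriskError("duplicate feature ids in weight set")
        if not np.isfinite(self.entries["weight"].to_numpy(dtype=float)).all():
            raise MesoriskError("weights must be finite")

    @property
    def n_variants(self) -> int:
        return len(self.entries)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    weights: WeightSet,
    target_variants: pd.DataFrame,
    drop_palindromic: bool = True,
    max_abs_beta: float | None = 0.5,
) -> tuple[WeightSet, dict]:
    """Align external weights to the target's ref/alt coding.

    Weights whose effect allele equals the target *ref* get their sign
    flipped (and alleles swapped) so that every retained weight is per
    alt-allele dose.  A/T and C/G (palindromic) sites and large-effect sites
    (|beta| above ``max_abs_beta``) are dropped; incompatible allele pairs
    are dropped, never guessed.  The audit counts every rule.
    """
    audit = {
        "n_input": len(weights.entries),
        "n_missing_from_target": 0,
        "n_palindromic_dropped": 0,
        "n_large_effect_dropped": 0,
        "n_allele_mismatch_dropped": 0,
        "n_flipped": 0,
        "n_retained": 0,
    }
    rows = []
    for vid, row in weights.entries.iterrows():
        if vid not in target_variants.index:
            audit["n_missing_from_target"] += 1
            continue
        ea = str(row["effect_allele"])
        oa = str(row.get("other_allele", ""))
        w = float(row["weight"])
        ref = str(target_variants.loc[vid, "ref"])
        alt = str(target_variants.loc[vid, "alt"])
        if drop_palindromic and _is_palindromic(ref, alt):
            audit["n_palindromic_dropped"] += 1
            continue
        if ea == alt and (oa in ("", ref)):
            pass
        elif ea == ref and (oa in ("", alt)):
            w = -w
            ea, oa = alt, ref
            audit["n_flipped"] += 1
        else:
            audit["n_allele_mismatch_dropped"] += 1
            continue
        if max_abs_beta is not None and abs(w) > max_abs_beta:
            audit["n_large_effect_dropped"] += 1
            continue
        rows.append({"variant_id": vid, "effect_allele": ea, "other_allele": oa or ref, "weight": w})
    entries = (
        pd.DataFrame(rows).set_index("variant_id")
        if rows
        else pd.DataFrame(columns=["effect_allele", "other_allele", "weight"])
    )
    audit["n_retained"] = len(entries)
    return WeightSet(entries=entries, source_threshold=weights.source_threshold), audit


def ld_clump(
    stats_table: pd.DataFrame,
    reference: GenotypeMatrix,
    r2_max: float = 0.1,
    window_bp: int = 250_000,
) -> tuple[list[str], dict]:
    """Greedy p-value clumping against a genotype reference.

    Repeatedly takes the lowest-p unassigned variant as the index and removes
    all unassigned variants on the same chromosome within ``window_bp`` whose
    dosage r-squared with the index reaches ``r2_max``.  P ties break by
    (chromosome, position) ascending.  r-squared is the squared Pearson
    correlation of dosages on pairwise-complete samples.
    """
    present = stats_table["variant_id"].isin(reference.variant_ids)
    n_missing = int((~present).sum())
    if n_missing:
        logger.info("ld_clump: %d variants missing from reference excluded", n_missing)
    t = stats_table.loc[present].copy()
    t = t.sort_values(
        ["p_value", "chromosome", "base_pair_location"], kind="stable"
    ).reset_index(drop=True)
    col = {v: reference.variant_ids.get_loc(v) for v in t["variant_id"]}
    chrom = t["chromosome"].astype(str).to_numpy()
    pos = t["base_pair_location"].to_numpy()
    vids = t["variant_id"].to_numpy()
    unassigned = np.ones(len(t), dtype=bool)
    retained: list[str] = []
    d = reference.dosages
    for i in range(len(t)):
        if not unassigned[i]:
            continue
        retained.append(vids[i])
        unassigned[i] = False
        near = np.flatnonzero(
            unassigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        )
        if near.size == 0:
            continue
        x = d[:, col[vids[i]]]
        ynear = d[:, [col[vids[j]] for j in near]]
        if np.isnan(x).any() or np.isnan(ynear).any():
            for idx_j, j in enumerate(near):
                y = ynear[:, idx_j]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                    continue
                if np.corrcoef(x[ok], y[ok])[0, 1] ** 2 >= r2_max:
                    unassigned[j] = False
        else:
            xc = x - x.mean()
            yc = ynear - ynear.mean(axis=0)
            denom = np.sqrt((xc @ xc) * (yc * yc).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (xc @ yc) / denom, 0.0)
            unassigned[near[r * r >= r2_max]] = False
    return retained, {"n_missing_from_reference": n_missing}


def score(genotypes: GenotypeMatrix, weights: WeightSet) -> RiskScoreSet:
    """Weighted allele-dosage sum per sample.

    Weights must already be harmonized to the target (effect allele = alt);
    missing dosages are imputed as twice the target-estimated allele
    frequency, keeping scores comparable across missingness patterns.
    """
    if len(weights.entries) == 0:
        raise MesoriskError("cannot score with an empty weight set")
    vids = weights.entries.index
    missing = [v for v in vids if v not in genotypes.variant_ids]
    if missing:
        raise MesoriskError(f"weight variants absent from genotypes: {missing[:5]}")
    sub = genotypes.subset_variants(vids)
    mism = sub.variants["alt"].to_numpy() != weights.entries["effect_allele"].to_numpy()
    if mism.any():
        raise MesoriskError(
            "weights are not harmonized to the target (effect allele != alt); "
            "run harmonize() first"
        )
    d = sub.dosages.copy()
    impute = 2.0 * (np.nanmean(d, axis=0) / 2.0)  # 2 * target-estimated allele frequency
    ind = np.where(np.isnan(d))
    d[ind] = np.take(impute, ind[1])
    w = weights.entries["weight"].to_numpy(dtype=float)
    s = d @ w
    return RiskScoreSet(
        scores=pd.Series(s, index=pd.Index(genotypes.samples, name="sample_id"), name="PRS"),
        features=weights.entries.reset_index(),
        name="PRS",
    )


@dataclass
class ThresholdReport:
    per_threshold: pd.DataFrame
    best_threshold: float
    best_weights: WeightSet


def threshold_scan(
    train_stats: pd.DataFrame,
    train_genotypes: GenotypeMatrix,
    test_genotypes: GenotypeMatrix,
    test_cohort: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    r2_max: float = 0.1,
    window_bp: int = 250_000,
) -> ThresholdReport:
    """Clump + threshold grid search, selecting the best-discriminating PRS.

    For each inclusion threshold the clumped training-set variants with
    p below the threshold define a weight set (training betas); the resulting
    raw test-set score is judged by AUC, with the two-sample K-S p-value
    between case and control scores as tie-breaker (then the smaller
    threshold).  Thresholds yielding no variants are recorded as degenerate
    and skipped in the selection.
    """
    if not thresholds:
        raise MesoriskError("threshold grid is empty")
    validate_cohort(test_cohort)
    overlap = set(train_genotypes.samples) & set(test_genotypes.samples)
    if overlap:
        raise MesoriskError(
            f"train and test genotype samples overlap ({len(overlap)} shared)"
        )
    retained, _ = ld_clump(train_stats, train_genotypes, r2_max=r2_max, window_bp=window_bp)
    clumped = train_stats.set_index("variant_id").loc[retained]
    status = test_cohort["status"].to_numpy(dtype=int)
    rows = []
    candidates = []
    for thr in sorted(thresholds):
        sel = clumped.loc[clumped["p_value"] < thr]
        if len(sel) == 0:
            rows.append(
                dict(threshold=thr, n_variants=0, auc=np.nan, ks_p=np.nan, degenerate=True)
            )
            continue
        ws = WeightSet(
            entries=pd.DataFrame(
                {
                    "effect_allele": sel["effect_allele"].to_numpy(),
                    "other_allele": sel["other_allele"].to_numpy(),
                    "weight": sel["beta"].to_numpy(),
                },
                index=sel.index,
            ),
            source_threshold=thr,
        )
        rs = score(test_genotypes, ws)
        s = rs.scores.to_numpy()
        auc, _, _ = auc_delong(s, status)
        _, ks_p = ks_two_sample(s[status == 1], s[status == 0])
        rows.append(dict(threshold=thr, n_variants=len(sel), auc=auc, ks_p=ks_p, degenerate=False))
        candidates.append((auc, -ks_p, -thr, ws))
    report = pd.DataFrame(rows)
    if not candidates:
        raise MesoriskError("every threshold yielded zero variants")
    # highest AUC; ties -> smaller K-S p; ties -> smaller threshold
    best = max(candidates, key=lambda c: (c[0], c[1], c[2]))
    return ThresholdReport(
        per_threshold=report, best_threshold=best[3].source_threshold, best_weights=best[3]
    )


def pc_normalize_scores(
    scores: pd.Series,
    reference_pcs: pd.DataFrame,
    reference_scores: pd.Series,
    target_pcs: pd.DataFrame,
) -> pd.Series:
    """Ancestry-adjust raw scores using reference PCs.

    A linear regression of the reference scores on the reference PCs defines
    the ancestry-predicted score; the target's adjusted score is the raw
    score minus that prediction, standardized by the reference residuals'
    mean and SD.
    """
    if list(reference_pcs.columns) != list(target_pcs.columns):
        raise MesoriskError("reference and target PC dimensionality differ")
    X = np.column_stack([np.ones(len(reference_pcs)), reference_pcs.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MesoriskError("rank-deficient PC design")
    y = reference_scores.loc[reference_pcs.index].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    mu, sd = resid.mean(), resid.std(ddof=1)
    if sd == 0:
        raise MesoriskError("reference residuals are constant; cannot standardize")
    Xt = np.column_stack([np.ones(len(target_pcs)), target_pcs.to_numpy(dtype=float)])
    adj = scores.loc[target_pcs.index].to_numpy(dtype=float) - Xt @ coef
    return pd.Series((adj - mu) / sd, index=target_pcs.index, name=scores.name)
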