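"""Sample QC, principal components, the per-variant association scan,
genomic inflation, and fixed-effect meta-analysis.

The scan fits one covariate-adjusted logistic regression per variant
(``status ~ dose + covariates``) by Newton/IRLS, batched across variants:
all variants share the response and covariate block, so the per-variant
Hessians are assembled with einsum and solved in one stacked call.  Wald
beta, SE and two-sided p are reported; non-converged or separated variants
are flagged, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .containers import GenotypeMatrix, MesoriskError, validate_cohort

logger = logging.getLogger("mesorisk")

_CHI2_MEDIAN_1DF = 0.4549364  # median of chi-square with 1 df


# ---------------------------------------------------------------------------
# Batched logistic regression
# ---------------------------------------------------------------------------

def _batched_logit(
    y: np.ndarray,
    covs: np.ndarray,
    doses: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``logit(y) ~ covs + dose_v`` for every dose column.

    Missing doses exclude the row for that variant only (mask trick: the
    masked weights/score contributions vanish, which is algebraically the fit
    on the complete rows).  Returns (beta, se, converged, separated) for the
    dose coefficient.
    """
    n, v = doses.shape
    p0 = covs.shape[1]
    p = p0 + 1
    mask = ~np.isnan(doses)
    d0 = np.nan_to_num(doses, nan=0.0)
    beta_out = np.empty(v)
    se_out = np.empty(v)
    conv_out = np.zeros(v, dtype=bool)
    sep_out = np.zeros(v, dtype=bool)

    chunk = max(1, int(2e7 / max(1, n * p)))
    for s in range(0, v, chunk):
        e = min(v, s + chunk)
        b = e - s
        X = np.empty((b, n, p))
        X[:, :, :p0] = covs[None, :, :]
        X[:, :, p0] = d0[:, s:e].T
        m = mask[:, s:e].T.astype(float)  # (b, n)
        X *= m[:, :, None]
        beta = np.zeros((b, p))
        converged = np.zeros(b, dtype=bool)
        H = None
        for _ in range(max_iter):
            eta = np.einsum("bnp,bp->bn", X, beta)
            mu = expit(eta)
            w = mu * (1.0 - mu) * m
            grad = np.einsum("bnp,bn->bp", X, (y[None, :] - mu) * m)
            converged = np.abs(grad).max(axis=1) < tol
            if converged.all():
                H = np.einsum("bnp,bn,bnq->bpq", X, w, X)
                break
            H = np.einsum("bnp,bn,bnq->bpq", X, w, X)
            ridge = 1e-12 * np.maximum(
                np.einsum("bpp->b", H), 1.0
            )  # keep near-separated fits solvable
            Hr = H + ridge[:, None, None] * np.eye(p)[None, :, :]
            try:
                step = np.linalg.solve(Hr, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = np.einsum("bpq,bq->bp", np.linalg.pinv(Hr), grad)
            step = np.clip(step, -10.0, 10.0)
            beta = beta + np.where(converged[:, None], 0.0, step)
        if H is None:
            H = np.einsum("bnp,bn,bnq->bpq", X, mu * (1 - mu) * m, X)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov_beta = np.linalg.pinv(H)
        se = np.sqrt(np.maximum(np.einsum("bpp->bp", cov_beta), 0.0))
        beta_out[s:e] = beta[:, p0]
        se_out[s:e] = se[:, p0]
        conv_out[s:e] = converged
        sep_out[s:e] = np.abs(beta).max(axis=1) > separation_bound
    return beta_out, se_out, conv_out, sep_out


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    kept_samples: list[str]
    flagged_related: list[tuple[str, str, float]] = field(default_factory=list)
    flagged_het: dict[str, float] = field(default_factory=dict)
    flagged_pca: dict[str, int] = field(default_factory=dict)

    @property
    def removed(self) -> set[str]:
        return (
            {r[0] for r in self.flagged_related}
            | set(self.flagged_het)
            | set(self.flagged_pca)
        )


def kinship_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Half the standardized-genotype relationship matrix.

    Phi_ij = (1/2M) sum_m (g_im - 2f_m)(g_jm - 2f_m) / (2 f_m (1 - f_m));
    duplicates/MZ pairs sit near 0.5, first-degree near 0.25.
    """
    d = genotypes.dosages
    f = np.nanmean(d, axis=0) / 2.0
    keep = (f > 0) & (f < 1)
    d = d[:, keep]
    f = f[keep]
    z = (np.nan_to_num(d, nan=0.0) - 2 * f) / np.sqrt(2 * f * (1 - f))
    z[np.isnan(d)] = 0.0
    m = z.shape[1]
    phi = (z @ z.T) / m / 2.0
    return pd.DataFrame(phi, index=genotypes.samples, columns=genotypes.samples)


def heterozygosity_rate(genotypes: GenotypeMatrix) -> pd.Series:
    d = genotypes.dosages
    het = np.nansum(d == 1, axis=1) / np.maximum((~np.isnan(d)).sum(axis=1), 1)
    return pd.Series(het, index=genotypes.samples, name="het_rate")


def qc_samples(
    genotypes: GenotypeMatrix,
    kinship_max: float = 0.125,
    het_sd: float = 3.0,
    pca_sd: float = 6.0,
    pca_max_iter: int = 5,
    n_pcs: int = 10,
) -> QcReport:
    """Flag related pairs, heterozygosity outliers and iterative-PCA outliers.

    For each related pair (kinship above ``kinship_max``) the member with the
    lower genotype call rate is removed (tie: the lexicographically later id).
    PCA outliers beyond ``pca_sd`` SD on any top PC are removed and the PCs
    recomputed, until no outlier remains or ``pca_max_iter`` rounds.
    """
    if genotypes.n_samples < 2:
        raise MesoriskError("QC needs at least 2 samples")
    if genotypes.n_variants < 50:
        raise MesoriskError(
            f"QC needs >= 50 variants for a stable kinship estimate, got {genotypes.n_variants}"
        )
    samples = list(genotypes.samples)
    phi = kinship_matrix(genotypes).to_numpy()
    call_rate = pd.Series(
        (~np.isnan(genotypes.dosages)).mean(axis=1), index=samples
    )
    flagged_related: list[tuple[str, str, float]] = []
    removed: set[str] = set()
    iu = np.triu_indices(len(samples), k=1)
    order = np.argsort(-phi[iu])
    for k in order:
        val = phi[iu[0][k], iu[1][k]]
        if val <= kinship_max:
            break
        a, b = samples[iu[0][k]], samples[iu[1][k]]
        if a in removed or b in removed:
            continue
        if call_rate[a] < call_rate[b]:
            drop, keep = a, b
        elif call_rate[b] < call_rate[a]:
            drop, keep = b, a
        else:
            drop, keep = max(a, b), min(a, b)
        flagged_related.append((drop, keep, float(val)))
        removed.add(drop)

    kept = [s for s in samples if s not in removed]
    sub = genotypes.subset_samples(
        np.array([samples.index(s) for s in kept])
    )
    het = heterozygosity_rate(sub)
    z = (het - het.mean()) / (het.std(ddof=1) if len(het) > 1 else 1.0)
    flagged_het = {s: float(z[s]) for s in het.index[np.abs(z) > het_sd]}
    kept = [s for s in kept if s not in flagged_het]

    flagged_pca: dict[str, int] = {}
    for it in range(1, pca_max_iter + 1):
        if len(kept) < 3:
            break
        sub = genotypes.subset_samples(np.array([samples.index(s) for s in kept]))
        k = min(n_pcs, len(kept) - 1, sub.n_variants)
        pcs = compute_pcs(sub, k)
        zz = (pcs - pcs.mean()) / pcs.std(ddof=1).replace(0.0, 1.0)
        out = pcs.index[(zz.abs() > pca_sd).any(axis=1)]
        if len(out) == 0:
            break
        for s in out:
            flagged_pca[s] = it
        kept = [s for s in kept if s not in flagged_pca]
    return QcReport(
        kept_samples=kept,
        flagged_related=flagged_related,
        flagged_het=flagged_het,
        flagged_pca=flagged_pca,
    )


def compute_pcs(genotypes: GenotypeMatrix, n_pcs: int) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant.  Components are ordered by
    decreasing variance; the sign convention makes each component's
    largest-magnitude variant loading positive.
    """
    max_rank = min(genotypes.n_samples - 1, genotypes.n_variants)
    if n_pcs > max_rank:
        raise MesoriskError(f"n_pcs={n_pcs} exceeds maximum rank {max_rank}")
    d = genotypes.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    ind = np.where(np.isnan(d))
    d[ind] = np.take(col_mean, ind[1])
    d -= d.mean(axis=0)
    sd = d.std(axis=0, ddof=0)
    nz = sd > 0
    d[:, nz] /= sd[nz]
    d[:, ~nz] = 0.0
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    return pd.DataFrame(
        scores, index=pd.Index(genotypes.samples, name="sample_id"),
        columns=[f"PC{i+1}" for i in range(n_pcs)],
    )


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    table: pd.DataFrame
    n_excluded_maf_mac: int
    n_dropped_missing_covariates: int


def build_design(
    cohort: pd.DataFrame, covariate_names: list[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Expand named covariates to a numeric design (no intercept).

    ``sex`` becomes an M indicator; ``exposure`` becomes two dummies (low,
    high) vs none, and rows with missing exposure are marked for dropping.
    Returns (design, column names, keep-row mask).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    keep = np.ones(len(cohort), dtype=bool)
    for name in covariate_names:
        if name == "sex":
            cols.append((cohort["sex"].to_numpy() == "M").astype(float))
            names.append("sex_M")
        elif name == "exposure":
            expo = pd.to_numeric(cohort["exposure"], errors="coerce").to_numpy(dtype=float)
            keep &= ~np.isnan(expo)
            cols.append((expo == 1).astype(float))
            cols.append((expo == 2).astype(float))
            names.extend(["exposure_low", "exposure_high"])
        else:
            if name not in cohort.columns:
                raise MesoriskError(f"covariate {name!r} not in cohort table")
            v = pd.to_numeric(cohort[name], errors="coerce").to_numpy(dtype=float)
            keep &= ~np.isnan(v)
            cols.append(v)
            names.append(name)
    design = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return design, names, keep


def assoc_scan(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    covariate_names: list[str] | None = None,
    maf_min: float = 0.01,
    mac_min: int = 20,
) -> ScanResult:
    """Covariate-adjusted logistic association scan over all variants.

    Variants failing MAF/MAC thresholds are excluded and counted; rows with a
    missing covariate are dropped with a logged count; non-converged or
    separated fits are flagged in the output, not dropped.
    """
    validate_cohort(cohort)
    if list(cohort.index) != genotypes.samples:
        raise MesoriskError("cohort and genotype samples differ (or out of order)")
    covariate_names = list(covariate_names or [])
    design, names, keep = build_design(cohort, covariate_names)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("assoc_scan: dropped %d rows with missing covariates", n_drop)
    y = cohort["status"].to_numpy(dtype=float)[keep]
    if len(np.unique(y)) < 2:
        raise MesoriskError("status is constant in the analysis sample")
    covs = np.column_stack([np.ones(keep.sum()), design[keep]])
    if covs.shape[1] > 1 and np.linalg.matrix_rank(covs) < covs.shape[1]:
        raise MesoriskError(f"collinear covariates among {names}")
    doses = genotypes.dosages[keep]

    af = np.nanmean(doses, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    n_called = (~np.isnan(doses)).sum(axis=0)
    mac = np.round(maf * 2 * n_called).astype(int)
    ok = (maf >= maf_min) & (mac >= mac_min)
    n_excl = int((~ok).sum())

    sub = doses[:, ok]
    beta, se, conv, sep = _batched_logit(y, covs, sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    meta = genotypes.variants.loc[ok]
    table = pd.DataFrame(
        {
            "variant_id": meta.index,
            "chromosome": meta["chromosome"].to_numpy(),
            "base_pair_location": meta["position"].to_numpy(),
            "effect_allele": meta["alt"].to_numpy(),
            "other_allele": meta["ref"].to_numpy(),
            "beta": beta,
            "standard_error": se,
            "p_value": p,
            "effect_allele_frequency": af[ok],
            "n": n_called[ok],
            "converged": conv,
            "separated": sep,
        }
    ).reset_index(drop=True)
    return ScanResult(
        table=table,
        n_excluded_maf_mac=n_excl,
        n_dropped_missing_covariates=n_drop,
    )


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median association chi-square over its null
    expectation (0.4549...)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise MesoriskError("no p-values supplied")
    if p.size < 20:
        raise MesoriskError(f"need >= 20 p-values for a stable lambda, got {p.size}")
    if (p <= 0).any() or (p > 1).any():
        raise MesoriskError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_MEDIAN_1DF)


# ---------------------------------------------------------------------------
# Fixed-effect inverse-variance meta-analysis
# ---------------------------------------------------------------------------

def meta_fixed(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, dict]:
    """Inverse-variance fixed-effect meta-analysis with Cochran's Q and
    Higgins' I-squared.

    Variants are matched on id with alleles harmonized to the first study
    carrying them (effect/other swapped -> flip the sign; any other allele
    pair is dropped and counted).  Variants present in a single study are
    passed through flagged, not pooled.
    """
    if len(tables) < 2:
        raise MesoriskError("meta-analysis needs >= 2 studies")
    n_mismatch = 0
    per_variant: dict[str, list[tuple[float, float]]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    passthrough: dict[str, dict] = {}
    for t in tables:
        for row in t.itertuples(index=False):
            vid = row.variant_id
            ea, oa = row.effect_allele, row.other_allele
            b, s = float(row.beta), float(row.standard_error)
            if vid not in alleles:
                alleles[vid] = (ea, oa)
                per_variant[vid] = [(b, s)]
                passthrough[vid] = {
                    "chromosome": row.chromosome,
                    "base_pair_location": row.base_pair_location,
                    "effect_allele": ea,
                    "other_allele": oa,
                }
            else:
                ref_ea, ref_oa = alleles[vid]
                if (ea, oa) == (ref_ea, ref_oa):
                    per_variant[vid].append((b, s))
                elif (ea, oa) == (ref_oa, ref_ea):
                    per_variant[vid].append((-b, s))
                else:
                    n_mismatch += 1
    rows = []
    for vid, studies in per_variant.items():
        b = np.array([x[0] for x in studies])
        s = np.array([x[1] for x in studies])
        base = passthrough[vid]
        if len(studies) == 1:
            rows.append(
                dict(
                    variant_id=vid,
                    **base,
                    pooled_beta=b[0],
                    pooled_se=s[0],
                    z=b[0] / s[0],
                    p=2 * stats.norm.sf(abs(b[0] / s[0])),
                    q_stat=np.nan,
                    df=0,
                    i2=np.nan,
                    het_p=np.nan,
                    n_studies=1,
                    flag="single_study",
                )
            )
            continue
        w = 1.0 / s**2
        pooled = float((w * b).sum() / w.sum())
        pooled_se = float(1.0 / np.sqrt(w.sum()))
        q = float((w * (b - pooled) ** 2).sum())
        df = len(studies) - 1
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        het_p = float(stats.chi2.sf(q, df))
        z = pooled / pooled_se
        rows.append(
            dict(
                variant_id=vid,
                **base,
                pooled_beta=pooled,
                pooled_se=pooled_se,
                z=z,
                p=2 * stats.norm.sf(abs(z)),
                q_stat=q,
                df=df,
                i2=i2,
                het_p=het_p,
                n_studies=len(studies),
                flag="",
            )
        )
    out = pd.DataFrame(rows)
    return out, {"n_allele_mismatch_dropped": n_mismatch}
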