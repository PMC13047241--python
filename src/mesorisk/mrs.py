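"""Differential methylation and the methylation risk score.

Beta-values are analysed directly (no M-value transform): per CpG a linear
model ``beta ~ status + covariates`` gives the adjusted case-control
difference on the beta scale; CpGs passing the effect-size and FDR filters
carry their effect estimate as MRS weight.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MesoriskError, MethylationMatrix, RiskScoreSet, validate_cohort
from .assoc import build_design
from .prs import WeightSet

logger = logging.getLogger("mesorisk")


def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the common distribution of mean order
    statistics, preserving within-sample ranks; ties share the mean of the
    values they would have received."""
    v = matrix.values
    if np.isnan(v).all(axis=1).any():
        raise MesoriskError("all-missing sample in methylation matrix")
    n, m = v.shape
    mean_sorted = np.sort(v, axis=1).mean(axis=0)
    out = np.empty_like(v)
    for i in range(n):
        order = np.argsort(v[i], kind="stable")
        sv = v[i][order]
        vals = mean_sorted
        if (np.diff(sv) == 0).any():  # ties share the mean of their slots
            vals = mean_sorted.copy()
            j = 0
            while j < m:
                k = j
                while k + 1 < m and sv[k + 1] == sv[j]:
                    k += 1
                if k > j:
                    vals[j : k + 1] = vals[j : k + 1].mean()
                j = k + 1
        ranked = np.empty(m)
        ranked[order] = vals
        out[i] = ranked
    return MethylationMatrix(samples=matrix.samples, cpg_ids=matrix.cpg_ids, values=out)


def dm_scan(
    matrix: MethylationMatrix,
    cohort: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-CpG linear model of beta-values on status and covariates.

    All CpGs share a design, so coefficients are obtained for the whole
    matrix in one least-squares solve.  Returns effect (status coefficient),
    SE, p (t-test), q (Benjamini-Hochberg across all tested CpGs), direction
    (hyper = higher in cases) and a zero-variance flag.
    """
    validate_cohort(cohort)
    if list(cohort.index) != matrix.samples:
        raise MesoriskError("cohort and methylation samples differ (or out of order)")
    covariate_names = list(covariate_names or [])
    design, names, keep = build_design(cohort, covariate_names)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dm_scan: dropped %d rows with missing covariates", n_drop)
    y01 = cohort["status"].to_numpy(dtype=float)[keep]
    if len(np.unique(y01)) < 2:
        raise MesoriskError("status is constant in the analysis sample")
    X = np.column_stack([np.ones(keep.sum()), y01, design[keep]])
    colnames = ["intercept", "status"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        pair = None
        for a in range(corr.shape[0]):
            for b in range(a + 1, corr.shape[0]):
                if abs(corr[a, b]) > 1 - 1e-10:
                    pair = (colnames[1 + a], colnames[1 + b])
        raise MesoriskError(f"collinear covariates: {pair or colnames[1:]}")
    Y = matrix.values[keep]
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ Y)  # (p, m)
    resid = Y - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(xtx_inv[1, 1] * sigma2, 0.0))
    effect = coef[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = effect / se
        pval = 2.0 * stats.t.sf(np.abs(tval), df=dof)
    case = y01 == 1
    zero_var = (Y[case].std(axis=0) == 0) | (Y[~case].std(axis=0) == 0)
    pval = np.where(np.isnan(pval), 1.0, pval)
    _, qval, _, _ = multipletests(pval, method="fdr_bh")
    return pd.DataFrame(
        {
            "cpg_id": matrix.cpg_ids,
            "effect": effect,
            "se": se,
            "p": pval,
            "q": qval,
            "direction": np.where(effect > 0, "hyper", "hypo"),
            "zero_variance": zero_var,
        }
    ).reset_index(drop=True)


def select_cpgs(
    results: pd.DataFrame,
    min_abs_effect: float = 0.10,
    max_q: float = 0.05,
) -> tuple[WeightSet, dict]:
    """CpGs with |effect| strictly above ``min_abs_effect`` and FDR q below
    ``max_q``; the effect estimate becomes the MRS weight."""
    if len(results) == 0:
        raise MesoriskError("empty differential-methylation results")
    sel = results.loc[
        (results["effect"].abs() > min_abs_effect) & (results["q"] < max_q)
    ]
    counts = {
        "n_selected": len(sel),
        "n_hypo": int((sel["effect"] < 0).sum()),
        "n_hyper": int((sel["effect"] > 0).sum()),
    }
    if len(sel) == 0:
        raise MesoriskError(
            "no CpGs pass the effect-size/FDR filters; MRS cannot be built"
        )
    entries = pd.DataFrame(
        {"weight": sel["effect"].to_numpy()},
        index=pd.Index(sel["cpg_id"], name="cpg_id"),
    )
    return WeightSet(entries=entries, kind="cpg"), counts


def mrs_score(
    matrix: MethylationMatrix,
    weights: WeightSet,
    unit_weights: bool = False,
) -> RiskScoreSet:
    """Weighted sum of beta-values over selected CpGs, z-standardized within
    the dataset.

    Missing CpGs are imputed at the cohort mean with a warning;
    ``unit_weights=True`` replaces effect-size weights by their sign.
    """
    if len(weights.entries) == 0:
        raise MesoriskError("cannot score with an empty weight set")
    w = weights.entries["weight"].to_numpy(dtype=float)
    if unit_weights:
        w = np.sign(w)
    cols = matrix.cpg_ids.get_indexer(weights.entries.index)
    found = cols >= 0
    if not found.all():
        logger.warning(
            "mrs_score: %d weight CpGs absent; cohort-mean imputation applied",
            int((~found).sum()),
        )
    vals = np.empty((matrix.n_samples, len(w)))
    vals[:, found] = matrix.values[:, cols[found]]
    if (~found).any():
        # absent CpG contributes its (unknown) cohort mean: a constant shift,
        # removed by the z-standardization below; use overall mean beta
        vals[:, ~found] = matrix.values.mean()
    col_mean = np.nanmean(vals, axis=0)
    ind = np.where(np.isnan(vals))
    vals[ind] = np.take(col_mean, ind[1])
    raw = vals @ w
    sd = raw.std(ddof=1)
    z = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    return RiskScoreSet(
        scores=pd.Series(z, index=pd.Index(matrix.samples, name="sample_id"), name="MRS"),
        features=weights.entries.reset_index(),
        name="MRS",
    )
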