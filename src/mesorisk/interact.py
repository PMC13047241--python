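"""SNP-by-asbestos-exposure interaction analysis.

Multiplicative-scale interaction via the product term of a logistic model,
exposure-stratified odds ratios, and additive-scale interaction via the
relative excess risk due to interaction (RERI) with a delta-method CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MesoriskError, validate_cohort
from .assoc import build_design
from .riskeval import SEPARATION_BOUND, _fit_logit

logger = logging.getLogger("mesorisk")


def interaction_scan(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    covariate_names: list[str] | None = None,
    exposure_coding: str = "binary",
) -> pd.DataFrame:
    """Per-variant logistic product-term test of dose-by-exposure interaction.

    ``status ~ dose + exposure + dose:exposure + covariates`` with exposure
    binarized any-vs-none by default (``exposure_coding='3level'`` uses two
    dummies and two product terms; the reported Wald test is then the
    smallest-p product term).  Variants with constant dose are flagged as
    inestimable.
    """
    validate_cohort(cohort)
    if list(cohort.index) != genotypes.samples:
        raise MesoriskError("cohort and genotype samples differ (or out of order)")
    covariate_names = [c for c in (covariate_names or []) if c != "exposure"]
    design, names, keep = build_design(cohort, covariate_names)
    expo = pd.to_numeric(cohort["exposure"], errors="coerce").to_numpy(dtype=float)
    keep &= ~np.isnan(expo)
    y = cohort["status"].to_numpy(dtype=float)
    rows = []
    for j, vid in enumerate(genotypes.variant_ids):
        dose = genotypes.dosages[:, j]
        k = keep & ~np.isnan(dose)
        d, e, yy = dose[k], expo[k], y[k]
        if np.nanstd(d) == 0:
            rows.append(dict(variant_id=vid, beta_gxe=np.nan, se=np.nan, p=np.nan,
                             flag="constant_dose"))
            continue
        if exposure_coding == "binary":
            eb = (e > 0).astype(float)
            X = np.column_stack([np.ones(k.sum()), d, eb, d * eb, design[k]])
            terms = [3]
        elif exposure_coding == "3level":
            e1, e2 = (e == 1).astype(float), (e == 2).astype(float)
            X = np.column_stack(
                [np.ones(k.sum()), d, e1, e2, d * e1, d * e2, design[k]]
            )
            terms = [4, 5]
        else:
            raise MesoriskError(f"unknown exposure_coding {exposure_coding!r}")
        flag = ""
        strata = ((e > 0).astype(int) if exposure_coding == "binary" else e)
        for level in np.unique(strata):
            if (yy[strata == level] == 1).sum() == 0:
                flag = "stratum_without_cases"
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append(dict(variant_id=vid, beta_gxe=np.nan, se=np.nan, p=np.nan,
                             flag=(flag + ";" if flag else "") + "inestimable"))
            continue
        res = _fit_logit(yy, X)
        best = min(
            terms,
            key=lambda t: 2 * stats.norm.sf(abs(res.params[t] / res.bse[t]))
            if res.bse[t] > 0 else 1.0,
        )
        b, se = float(res.params[best]), float(res.bse[best])
        p = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan
        if abs(b) > SEPARATION_BOUND:
            flag = (flag + ";" if flag else "") + "separation"
        rows.append(dict(variant_id=vid, beta_gxe=b, se=se, p=p, flag=flag))
    return pd.DataFrame(rows)


def stratified_or(
    dose: pd.Series,
    cohort: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-exposure-stratum odds ratio for carrying the variant.

    Without covariates this is the carrier (dose >= 1) 2x2 sample OR with a
    Woolf CI; with covariates a per-stratum logistic model on the dose.
    Strata with any 2x2 cell below 5 are annotated; empty strata are skipped
    with a warning.
    """
    validate_cohort(cohort)
    d = dose.loc[cohort.index].to_numpy(dtype=float)
    status = cohort["status"].to_numpy(dtype=int)
    expo = pd.to_numeric(cohort["exposure"], errors="coerce").to_numpy(dtype=float)
    covariate_names = [c for c in (covariate_names or []) if c != "exposure"]
    rows = []
    for s in (0.0, 1.0, 2.0):
        sel = (expo == s) & ~np.isnan(d)
        if sel.sum() == 0:
            logger.warning("stratified_or: exposure stratum %d empty; skipped", int(s))
            continue
        carrier = (d[sel] >= 1).astype(int)
        y = status[sel]
        a = int(((carrier == 1) & (y == 1)).sum())
        b = int(((carrier == 1) & (y == 0)).sum())
        c = int(((carrier == 0) & (y == 1)).sum())
        dd = int(((carrier == 0) & (y == 0)).sum())
        small = min(a, b, c, dd) < 5
        if carrier.std() == 0:
            rows.append(dict(exposure=int(s), or_estimate=np.nan, ci_low=np.nan,
                             ci_high=np.nan, n=int(sel.sum()),
                             flag="no_carriers" if carrier.max() == 0 else "all_carriers"))
            continue
        if not covariate_names:
            if b * c == 0 or a * dd == 0:
                rows.append(dict(exposure=int(s), or_estimate=np.inf if b * c == 0 and a * dd > 0 else np.nan,
                                 ci_low=np.nan, ci_high=np.nan, n=int(sel.sum()),
                                 flag="zero_cell"))
                continue
            log_or = np.log(a * dd / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / dd)
        else:
            design, _, keep = build_design(cohort.loc[sel], covariate_names)
            X = np.column_stack([np.ones(int(keep.sum())), d[sel][keep], design[keep]])
            res = _fit_logit(y[keep].astype(float), X)
            log_or, se = float(res.params[1]), float(res.bse[1])
        rows.append(
            dict(
                exposure=int(s),
                or_estimate=float(np.exp(log_or)),
                ci_low=float(np.exp(log_or - 1.96 * se)),
                ci_high=float(np.exp(log_or + 1.96 * se)),
                n=int(sel.sum()),
                flag="small_cells" if small else "",
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ReriResult:
    reri: float
    ci_low: float
    ci_high: float
    or10: float  # G only vs neither
    or01: float  # E only vs neither
    or11: float  # both vs neither
    classification: str
    se: float
    method: str = "delta"


def reri(
    cohort: pd.DataFrame,
    g_indicator,
    e_indicator,
    covariate_names: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> ReriResult:
    """Relative excess risk due to interaction for binary G and E.

    From ``logit(status) ~ G + E + G*E + covariates``: OR10 = exp(bG),
    OR01 = exp(bE), OR11 = exp(bG + bE + bGE) and
    RERI = OR11 - OR10 - OR01 + 1.  The 95% CI uses the delta method on the
    fitted coefficient covariance; under separation a bootstrap percentile CI
    is substituted with a warning.  RERI < 0 indicates antagonism (joint
    effect below additivity), > 0 super-additivity.
    """
    validate_cohort(cohort)
    g = np.asarray(g_indicator, dtype=float)
    e = np.asarray(e_indicator, dtype=float)
    if not set(np.unique(g[~np.isnan(g)])) <= {0.0, 1.0}:
        raise MesoriskError("G must be a binary carrier indicator")
    if not set(np.unique(e[~np.isnan(e)])) <= {0.0, 1.0}:
        raise MesoriskError("E must be a binary exposure indicator")
    design, names, keep = build_design(cohort, list(covariate_names or []))
    keep &= ~np.isnan(g) & ~np.isnan(e)
    if ((g == 0) & (e == 0) & keep).sum() == 0:
        raise MesoriskError("doubly-unexposed reference cell is empty")
    y = cohort["status"].to_numpy(dtype=float)[keep]
    gg, ee = g[keep], e[keep]
    X = np.column_stack([np.ones(keep.sum()), gg, ee, gg * ee, design[keep]])
    res = _fit_logit(y, X)
    bg, be, bge = res.params[1], res.params[2], res.params[3]
    or10, or01, or11 = np.exp(bg), np.exp(be), np.exp(bg + be + bge)
    point = float(or11 - or10 - or01 + 1.0)
    separated = bool(np.abs(res.params).max() > SEPARATION_BOUND)
    if not separated:
        grad = np.zeros(X.shape[1])
        grad[1] = or11 - or10
        grad[2] = or11 - or01
        grad[3] = or11
        cov = np.asarray(res.cov_params())
        se = float(np.sqrt(grad @ cov @ grad))
        ci = (point - 1.96 * se, point + 1.96 * se)
        method = "delta"
    else:
        logger.warning("reri: separation detected; bootstrap percentile CI used")
        rng = np.random.default_rng(seed)
        n = len(y)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) < 2:
                continue
            try:
                rb = _fit_logit(y[idx], X[idx])
            except Exception:
                continue
            boots.append(
                float(
                    np.exp(rb.params[1] + rb.params[2] + rb.params[3])
                    - np.exp(rb.params[1])
                    - np.exp(rb.params[2])
                    + 1.0
                )
            )
        if len(boots) < 10:
            ci, se = (np.nan, np.nan), np.nan
        else:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))
            se = float(np.std(boots, ddof=1))
        method = "bootstrap"
    if abs(point) < 1e-12:
        cls = "additive"
    elif point < 0:
        cls = "antagonistic"
    else:
        cls = "super-additive"
    return ReriResult(
        reri=point,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        or10=float(or10),
        or01=float(or01),
        or11=float(or11),
        classification=cls,
        se=se,
        method=method,
    )
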