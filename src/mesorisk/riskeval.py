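"""Risk-model fitting and comparison.

Covers the evaluation layer: logistic risk models with pseudo-R-squared,
AUC with DeLong variance and paired DeLong model comparison, two-sample
Kolmogorov-Smirnov, percentile-threshold odds ratios, sensitivity and
specificity at a score percentile, categorical net reclassification
improvement, Fisher's exact test, stratified Wilcoxon rank-sum tests, and
combined PRS/MRS tercile risk groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import MesoriskError, validate_cohort

logger = logging.getLogger("mesorisk")

SEPARATION_BOUND = 15.0  # |coefficient| beyond this flags (quasi-)separation


# ---------------------------------------------------------------------------
# Logistic model fitting
# ---------------------------------------------------------------------------

def _fit_logit(y: np.ndarray, X: np.ndarray):
    """statsmodels Logit fit with a BFGS fallback under separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=50, disp=0)
        except Exception:
            res = model.fit(method="bfgs", maxiter=500, disp=0)
    return res


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    fitted: pd.Series
    loglike: float
    loglike_null: float
    mcfadden: float
    nagelkerke: float
    auc: float
    auc_ci: tuple[float, float]
    separation_flag: bool
    n_dropped_missing: int

    @property
    def predictors(self) -> list[str]:
        return [p for p in self.params.index if p != "intercept"]


def _expand_predictors(
    cohort: pd.DataFrame,
    predictors: list[str],
    prs: pd.Series | None,
    mrs: pd.Series | None,
) -> tuple[pd.DataFrame, np.ndarray]:
    cols = {}
    keep = np.ones(len(cohort), dtype=bool)
    for p in predictors:
        key = p.replace("×", "x").replace("*", "x").replace(":", "x").upper()
        if p == "age":
            cols["age"] = pd.to_numeric(cohort["age"]).to_numpy(dtype=float)
        elif p == "sex":
            cols["sex_M"] = (cohort["sex"].to_numpy() == "M").astype(float)
        elif p == "exposure":
            expo = pd.to_numeric(cohort["exposure"], errors="coerce").to_numpy(dtype=float)
            keep &= ~np.isnan(expo)
            cols["exposure_low"] = (expo == 1).astype(float)
            cols["exposure_high"] = (expo == 2).astype(float)
        elif key == "PRS":
            if prs is None:
                raise MesoriskError("PRS requested but no PRS scores supplied")
            cols["PRS"] = prs.loc[cohort.index].to_numpy(dtype=float)
        elif key == "MRS":
            if mrs is None:
                raise MesoriskError("MRS requested but no MRS scores supplied")
            cols["MRS"] = mrs.loc[cohort.index].to_numpy(dtype=float)
        elif key == "PRSXMRS":
            if prs is None or mrs is None:
                raise MesoriskError("PRSxMRS requested but scores missing")
            cols["PRSxMRS"] = (
                prs.loc[cohort.index].to_numpy(dtype=float)
                * mrs.loc[cohort.index].to_numpy(dtype=float)
            )
        else:
            raise MesoriskError(f"unknown predictor {p!r}")
    return pd.DataFrame(cols, index=cohort.index), keep


def fit_risk_model(
    cohort: pd.DataFrame,
    predictors: list[str],
    prs: pd.Series | None = None,
    mrs: pd.Series | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic risk model.

    ``predictors`` may include ``age, sex, exposure, PRS, MRS, PRSxMRS``;
    exposure enters as two indicators (low, high) vs none and rows with
    missing exposure are dropped with a logged count.  Reports McFadden and
    Nagelkerke pseudo-R-squared and the AUC of the fitted probabilities
    with its DeLong CI.
    """
    validate_cohort(cohort)
    design, keep = _expand_predictors(cohort, predictors, prs, mrs)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("fit_risk_model: dropped %d rows with missing exposure", n_drop)
    sub = cohort.loc[keep]
    y = sub["status"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), design.loc[keep].to_numpy(dtype=float)])
    names = ["intercept"] + list(design.columns)
    res = _fit_logit(y, X)
    fitted = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
    ll = float(res.llf)
    p0 = y.mean()
    ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
    n = len(y)
    mcfadden = 1.0 - ll / ll0 if ll0 != 0 else 0.0
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = (1.0 - np.exp(2.0 * (ll0 - ll) / n)) / denom if denom != 0 else 0.0
    auc, var, ci = auc_delong(fitted, y.astype(int))
    sep = bool(np.abs(res.params).max() > SEPARATION_BOUND)
    if sep:
        logger.warning("fit_risk_model: separation suspected (|coef| > %.0f)", SEPARATION_BOUND)
    return ModelFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        fitted=pd.Series(fitted, index=sub.index, name="p_hat"),
        loglike=ll,
        loglike_null=ll0,
        mcfadden=max(0.0, mcfadden),
        nagelkerke=max(0.0, nagelkerke),
        auc=auc,
        auc_ci=ci,
        separation_flag=sep,
        n_dropped_missing=n_drop,
    )


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------

def _delong_components(scores: np.ndarray, status: np.ndarray):
    x = scores[status == 1]  # cases
    y = scores[status == 0]
    if len(x) == 0 or len(y) == 0:
        raise MesoriskError("both classes must be non-empty")
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01


def auc_delong(scores, status) -> tuple[float, float, tuple[float, float]]:
    """AUC (Mann-Whitney with ties counted 1/2) with DeLong variance and a
    95% CI truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    v10, v01 = _delong_components(scores, status)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    sd = np.sqrt(var)
    ci = (max(0.0, auc - 1.96 * sd), min(1.0, auc + 1.96 * sd))
    return auc, float(var), ci


def delong_compare(probs_a, probs_b, status) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (AUC_a - AUC_b, z, two-sided p); a degenerate zero-variance
    difference with equal AUCs gives p = 1.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    status = np.asarray(status, dtype=int)
    if a.shape != b.shape:
        raise MesoriskError("paired DeLong needs the same samples for both models")
    v10a, v01a = _delong_components(a, status)
    v10b, v01b = _delong_components(b, status)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    delta = float(auc_a - auc_b)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        return delta, 0.0, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return delta, float(z), float(p)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample K-S: D = sup |ECDF difference|, asymptotic Kolmogorov p
    with effective n = n1 n2 / (n1 + n2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise MesoriskError("both samples must have size >= 1")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(min(1.0, res.pvalue))


# ---------------------------------------------------------------------------
# Percentile thresholds
# ---------------------------------------------------------------------------

@dataclass
class PercentileOrRow:
    percentile: float
    or_estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_above_cases: int
    n_above_controls: int
    separation_flag: bool = False


def percentile_or(
    score: pd.Series,
    cohort: pd.DataFrame,
    covariate_names: list[str] | None = None,
    percentiles: tuple[float, ...] = (80, 90, 95),
    reference: str = "combined",
) -> list[PercentileOrRow]:
    """Odds ratio of being above each score percentile vs below.

    Thresholds come from the combined evaluation sample by default
    (``reference='controls'`` uses controls only); the OR is the indicator
    coefficient of a covariate-adjusted logistic model, Wald CI on the log
    scale.  Empty cells flag separation and the CI is reported unbounded.
    """
    validate_cohort(cohort)
    s = score.loc[cohort.index].to_numpy(dtype=float)
    status = cohort["status"].to_numpy(dtype=int)
    ref = s if reference == "combined" else s[status == 0]
    from .assoc import build_design

    design, names, keep = build_design(cohort, list(covariate_names or []))
    rows = []
    for q in percentiles:
        thr = np.percentile(ref, q)
        above = (s >= thr).astype(float)
        n_case = int(((above == 1) & (status == 1) & keep).sum())
        n_ctrl = int(((above == 1) & (status == 0) & keep).sum())
        sep = (
            n_case == 0
            or n_ctrl == 0
            or ((above == 0) & (status == 1) & keep).sum() == 0
            or ((above == 0) & (status == 0) & keep).sum() == 0
        )
        X = np.column_stack([np.ones(int(keep.sum())), above[keep], design[keep]])
        res = _fit_logit(status[keep].astype(float), X)
        b, se = float(res.params[1]), float(res.bse[1])
        if sep or abs(b) > SEPARATION_BOUND:
            logger.warning("percentile_or: separation at the %sth percentile", q)
            rows.append(
                PercentileOrRow(
                    percentile=q,
                    or_estimate=float(np.exp(b)),
                    ci_low=0.0,
                    ci_high=np.inf,
                    p=np.nan,
                    n_above_cases=n_case,
                    n_above_controls=n_ctrl,
                    separation_flag=True,
                )
            )
            continue
        rows.append(
            PercentileOrRow(
                percentile=q,
                or_estimate=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p=float(2 * stats.norm.sf(abs(b / se))),
                n_above_cases=n_case,
                n_above_controls=n_ctrl,
            )
        )
    return rows


def sens_spec_at(score, status, percentile: float = 80) -> tuple[float, float]:
    """Sensitivity / specificity of calling 'high risk' above the given
    percentile of the combined score distribution."""
    score = np.asarray(score, dtype=float)
    status = np.asarray(status, dtype=int)
    if (status == 1).sum() == 0 or (status == 0).sum() == 0:
        raise MesoriskError("both classes must be non-empty")
    thr = np.percentile(score, percentile)
    sens = float((score[status == 1] >= thr).mean())
    spec = float((score[status == 0] < thr).mean())
    return sens, spec


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

@dataclass
class NriResult:
    overall: float
    case_component: float
    control_component: float
    z: float
    p: float
    cut_points: tuple[float, float]
    table_cases: pd.DataFrame
    table_controls: pd.DataFrame


def _risk_category(p: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    lo, hi = cuts
    return (p >= lo).astype(int) + (p > hi).astype(int)


def nri_categorical(
    probs_old,
    probs_new,
    status,
    cut_points: tuple[float, float] = (0.20, 0.80),
) -> NriResult:
    """Categorical NRI with low/intermediate/high risk categories.

    Case component = P(up) - P(down) among cases; control component =
    P(down) - P(up) among controls; overall is their exact sum.  z uses the
    standard two-proportion variance.
    """
    po = np.asarray(probs_old, dtype=float)
    pn = np.asarray(probs_new, dtype=float)
    status = np.asarray(status, dtype=int)
    if po.shape != pn.shape or po.shape != status.shape:
        raise MesoriskError("NRI needs the same samples in both models")
    if (status == 1).sum() == 0 or (status == 0).sum() == 0:
        raise MesoriskError("empty status group")
    co = _risk_category(po, cut_points)
    cn = _risk_category(pn, cut_points)
    comps = {}
    var = 0.0
    tables = {}
    for g, sign in ((1, +1.0), (0, -1.0)):
        sel = status == g
        up = float((cn[sel] > co[sel]).mean())
        down = float((cn[sel] < co[sel]).mean())
        comps[g] = sign * (up - down)
        var += (up + down) / sel.sum()
        labels = ["low", "intermediate", "high"]
        tables[g] = pd.crosstab(
            pd.Categorical(np.array(labels)[co[sel]], categories=labels),
            pd.Categorical(np.array(labels)[cn[sel]], categories=labels),
            rownames=["old"], colnames=["new"], dropna=False,
        )
    overall = comps[1] + comps[0]
    if var > 0:
        z = overall / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    return NriResult(
        overall=overall,
        case_component=comps[1],
        control_component=comps[0],
        z=float(z),
        p=p,
        cut_points=cut_points,
        table_cases=tables[1],
        table_controls=tables[0],
    )


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test (minimum-likelihood rule) with the
    sample odds ratio ad/bc (0-cells give infinity semantics)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise MesoriskError("Fisher test needs a 2x2 table")
    if (t < 0).any() or not np.all(np.mod(t, 1) == 0):
        raise MesoriskError("counts must be non-negative integers")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        orr = np.nan if a * d == 0 else np.inf
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact(t.astype(int))
    return float(orr), float(p)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    idx = range(n1 + n2)
    ws = np.array([ranks[list(c)].sum() for c in combinations(idx, n1)])
    lo = (ws <= w_obs + 1e-9).mean()
    hi = (ws >= w_obs - 1e-9).mean()
    return float(w_obs), float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_stratified(score, status, strata) -> pd.DataFrame:
    """Case-control rank-sum comparison of a score within each stratum.

    Exact enumeration when n1 + n2 <= 12, otherwise the tie-corrected normal
    approximation.  Strata lacking one of the classes are skipped with a
    warning.
    """
    score = np.asarray(score, dtype=float)
    status = np.asarray(status, dtype=int)
    strata = np.asarray(strata)
    rows = []
    for s in pd.unique(strata[~pd.isna(strata)]):
        sel = strata == s
        x = score[sel & (status == 1)]
        y = score[sel & (status == 0)]
        if len(x) == 0 or len(y) == 0:
            logger.warning("wilcoxon_stratified: stratum %r lacks a class; skipped", s)
            continue
        if len(x) + len(y) <= 12:
            w, p = _exact_ranksum_p(x, y)
            method = "exact"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            w = float(res.statistic + len(x) * (len(x) + 1) / 2.0)
            p = float(res.pvalue)
            method = "normal"
        rows.append(dict(stratum=s, W=w, p=p, n_cases=len(x), n_controls=len(y), method=method))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Combined tercile risk groups
# ---------------------------------------------------------------------------

def tercile_risk_groups(
    prs: pd.Series,
    mrs: pd.Series,
    cohort: pd.DataFrame,
    rule: str = "both",
    percentile_cuts: tuple[float, float] = (33.0, 67.0),
) -> pd.DataFrame:
    """High vs intermediate odds ratio within each exposure stratum.

    Each score is cut at its own 33rd/67th percentiles; the combined group is
    high when both scores sit in the top tercile and low when both sit in the
    bottom tercile (``rule='either'`` instead requires just one score).
    Per exposure stratum, a logistic model with high/low indicators and the
    intermediate group as reference yields the OR; inestimable strata are
    flagged.
    """
    validate_cohort(cohort)
    p = prs.loc[cohort.index].to_numpy(dtype=float)
    m = mrs.loc[cohort.index].to_numpy(dtype=float)
    if np.isnan(p).any() or np.isnan(m).any():
        raise MesoriskError("both scores must be available for all samples")

    def terc(x):
        lo, hi = np.percentile(x, percentile_cuts)
        return (x >= lo).astype(int) + (x >= hi).astype(int)

    tp, tm = terc(p), terc(m)
    if rule == "both":
        group = np.where((tp == 2) & (tm == 2), 2, np.where((tp == 0) & (tm == 0), 0, 1))
    elif rule == "either":
        group = np.where((tp == 2) | (tm == 2), 2, np.where((tp == 0) & (tm == 0), 0, 1))
    else:
        raise MesoriskError(f"unknown rule {rule!r}")
    status = cohort["status"].to_numpy(dtype=int)
    expo = pd.to_numeric(cohort["exposure"], errors="coerce").to_numpy(dtype=float)
    rows = []
    for s in (0.0, 1.0, 2.0):
        sel = expo == s
        if sel.sum() == 0:
            continue
        g, y = group[sel], status[sel]
        estimable = (
            ((g == 2) & (y == 1)).any()
            and ((g == 2) & (y == 0)).any()
            and ((g == 1) & (y == 1)).any()
            and ((g == 1) & (y == 0)).any()
        )
        if not estimable:
            rows.append(
                dict(exposure=int(s), or_high_vs_intermediate=np.nan, ci_low=np.nan,
                     ci_high=np.nan, p=np.nan, n=int(sel.sum()), flag="inestimable")
            )
            continue
        X = np.column_stack([np.ones(sel.sum()), (g == 2).astype(float), (g == 0).astype(float)])
        res = _fit_logit(y.astype(float), X)
        b, se = float(res.params[1]), float(res.bse[1])
        rows.append(
            dict(
                exposure=int(s),
                or_high_vs_intermediate=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p=float(2 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan,
                n=int(sel.sum()),
                flag="separation" if abs(b) > SEPARATION_BOUND else "",
            )
        )
    return pd.DataFrame(rows)
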