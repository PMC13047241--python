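"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: block-LD
genotypes, Beta-distributed methylation with case-shifted CpGs, a three-level
occupational asbestos-exposure variable, and a logistic disease model with
genetic, epigenetic, exposure and gene-by-exposure effects.  Two sampling
designs are provided: a retrospective case-control draw and a 1:1
age/sex/exposure-matched nested case-control draw.

LD model
--------
Within a block, haplotypes are latent AR(1) Gaussians thresholded at the
allele-frequency quantile.  Thresholding attenuates correlation, so the latent
adjacent correlation is calibrated (via the exact bivariate-normal orthant
probability) such that the *realized genotype* correlation of adjacent
variants equals ``ld_rho``.  Across blocks, variants are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .containers import (
    GenotypeMatrix,
    MesoriskError,
    MethylationMatrix,
    PopulationSample,
    validate_cohort,
)

logger = logging.getLogger("mesorisk")

__all__ = [
    "VariantBlockSpec",
    "EffectSpec",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_phenotype",
    "sample_case_control",
    "sample_matched_nested",
]


@dataclass(frozen=True)
class VariantBlockSpec:
    """One LD block of variants on a chromosome."""

    n_variants: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.0
    chromosome: str = "1"
    start_pos: int = 1
    spacing: int = 5_000

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise MesoriskError("n_variants must be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise MesoriskError(
                f"require 0 < maf_low <= maf_high <= 0.5, got "
                f"({self.maf_low}, {self.maf_high})"
            )
        if not (0.0 <= self.ld_rho < 1.0):
            raise MesoriskError("ld_rho must lie in [0, 1)")
        if self.start_pos < 1 or self.spacing < 1:
            raise MesoriskError("positions are 1-based; start_pos and spacing must be >= 1")


@dataclass(frozen=True)
class EffectSpec:
    """Generating effects of the logistic disease model.

    ``status ~ Bernoulli(expit(alpha + sum beta_m * dose_m + gamma_E
    + sum gxe + age/sex terms))`` with exposure coded 0 = none, 1 = low,
    2 = high.  Methylation shifts ``delta`` act on the Beta mean of causal
    CpGs in cases.
    """

    causal_variants: dict[str, float] = field(default_factory=dict)
    causal_cpgs: dict[str, float] = field(default_factory=dict)
    exposure_log_ors: tuple[float, float] = (0.0, 0.0)  # (low vs none, high vs none)
    gxe_terms: tuple[tuple[str, int, float], ...] = ()
    baseline_logit: float = stats.norm().ppf(0.5)  # 0.0 -> 50% at reference
    age_log_or: float = 0.0  # per year, centred at the age mean
    sex_log_or: float = 0.0  # M vs F

    def __post_init__(self) -> None:
        values = (
            list(self.causal_variants.values())
            + list(self.causal_cpgs.values())
            + list(self.exposure_log_ors)
            + [g[2] for g in self.gxe_terms]
            + [self.baseline_logit, self.age_log_or, self.sex_log_or]
        )
        if not np.all(np.isfinite(values)):
            raise MesoriskError("all effect values must be finite")
        for vid, level, _ in self.gxe_terms:
            if level not in (1, 2):
                raise MesoriskError(f"gxe exposure level must be 1 or 2, got {level} for {vid}")


@lru_cache(maxsize=4096)
def _calibrated_latent_rho(target: float, q1: float, q2: float) -> float:
    """Latent bivariate-normal correlation whose thresholded indicators have
    (Pearson) correlation ``target`` at alt-allele frequencies q1, q2.

    Capped at the attainable maximum when the requested correlation cannot be
    realized for unequal allele frequencies.
    """
    if target <= 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(1.0 - q1), stats.norm.ppf(1.0 - q2)
    denom = np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))

    def phi(r: float) -> float:
        # P(Z1 > t1, Z2 > t2) = BVN CDF at (-t1, -t2) by central symmetry
        p11 = stats.multivariate_normal(cov=[[1.0, r], [r, 1.0]]).cdf([-t1, -t2])
        return (p11 - q1 * q2) / denom

    hi = 1.0 - 1e-9
    if phi(hi) <= target:
        return hi
    return float(optimize.brentq(lambda r: phi(r) - target, 0.0, hi, xtol=1e-6))


def simulate_genotypes(
    n_samples: int,
    blocks: list[VariantBlockSpec],
    seed: int,
    subpop_fst: float = 0.0,
    subpop_fraction: float = 0.5,
) -> GenotypeMatrix:
    """Draw hard-call dosages {0,1,2} with within-block AR(1)-style LD.

    Two independent haplotypes per sample share the block's latent correlation
    structure; the dosage is their sum, so variants are in Hardy-Weinberg
    proportions at their drawn allele frequency (uniform in
    ``[maf_low, maf_high]`` per variant).

    ``subpop_fst > 0`` splits samples into two subpopulations (the last
    ``subpop_fraction`` of rows) whose per-variant allele frequencies diverge
    from the drawn base frequency under a Balding-Nichols Beta model with the
    given fixation index; the default is a single homogeneous population.
    """
    if n_samples < 2:
        raise MesoriskError(f"n_samples must be >= 2, got {n_samples}")
    if not blocks:
        raise MesoriskError("at least one block is required")
    if not (0.0 <= subpop_fst < 1.0):
        raise MesoriskError("subpop_fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_sub2 = int(round(subpop_fraction * n_samples)) if subpop_fst > 0 else 0
    dosage_cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    last_pos: dict[str, int] = {}
    for b, block in enumerate(blocks):
        mafs = rng.uniform(block.maf_low, block.maf_high, size=block.n_variants)
        if n_sub2:
            # Balding-Nichols divergence of the two subpopulation frequencies
            a = mafs * (1.0 - subpop_fst) / subpop_fst
            bb = (1.0 - mafs) * (1.0 - subpop_fst) / subpop_fst
            f1 = np.clip(rng.beta(a, bb), 1e-4, 1 - 1e-4)
            f2 = np.clip(rng.beta(a, bb), 1e-4, 1 - 1e-4)
            freq = np.vstack(
                [np.tile(f1, (n_samples - n_sub2, 1)), np.tile(f2, (n_sub2, 1))]
            )
        else:
            freq = np.tile(mafs, (n_samples, 1))
        thresholds = stats.norm.ppf(1.0 - freq)  # (n_samples, n_variants)
        # latent haplotypes, AR(1) with per-pair calibrated correlation
        latent = np.empty((n_samples, 2, block.n_variants))
        latent[:, :, 0] = rng.standard_normal((n_samples, 2))
        for j in range(1, block.n_variants):
            r = _calibrated_latent_rho(
                block.ld_rho, round(float(mafs[j - 1]), 3), round(float(mafs[j]), 3)
            )
            eps = rng.standard_normal((n_samples, 2))
            latent[:, :, j] = r * latent[:, :, j - 1] + np.sqrt(1.0 - r * r) * eps
        dose = (latent > thresholds[:, None, :]).sum(axis=1).astype(float)
        dosage_cols.append(dose)
        start = block.start_pos
        if block.chromosome in last_pos and start <= last_pos[block.chromosome]:
            start = last_pos[block.chromosome] + block.spacing
        for j in range(block.n_variants):
            pos = start + j * block.spacing
            meta_rows.append(
                {
                    "variant_id": f"v{b}_{j}_{block.chromosome}_{pos}",
                    "chromosome": str(block.chromosome),
                    "position": pos,
                    "ref": "A",
                    "alt": "G",
                }
            )
        last_pos[block.chromosome] = pos
    variants = pd.DataFrame(meta_rows).set_index("variant_id")
    samples = [f"S{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=np.hstack(dosage_cols))


def simulate_methylation(
    cohort: pd.DataFrame,
    n_cpgs: int,
    causal_cpgs: dict[str, float] | None = None,
    precision: float = 50.0,
    seed: int = 0,
    baseline_mean_range: tuple[float, float] = (0.1, 0.9),
) -> MethylationMatrix:
    """Beta-distributed beta-values; causal CpGs have their mean shifted by
    ``delta`` in cases.

    A Beta(mean * precision, (1 - mean) * precision) draw per sample/CpG;
    larger ``precision`` means tighter beta-values around the mean.  CpG ids
    follow array-style naming (``cg`` prefix); causal ids must use the same
    scheme (``cg000000`` ... ).
    """
    validate_cohort(cohort)
    causal_cpgs = dict(causal_cpgs or {})
    if precision <= 0:
        raise MesoriskError("precision must be positive")
    lo, hi = baseline_mean_range
    if not (0.0 < lo < hi < 1.0):
        raise MesoriskError("baseline means must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    cpg_ids = pd.Index([f"cg{i:06d}" for i in range(n_cpgs)])
    unknown = [c for c in causal_cpgs if c not in cpg_ids]
    if unknown:
        raise MesoriskError(f"causal CpGs not in simulated set: {unknown[:5]}")
    base_means = rng.uniform(lo, hi, size=n_cpgs)
    status = cohort["status"].to_numpy(dtype=int)
    means = np.tile(base_means, (len(cohort), 1))
    for cpg, delta in causal_cpgs.items():
        j = cpg_ids.get_loc(cpg)
        shifted = base_means[j] + delta
        if not (0.0 < shifted < 1.0):
            raise MesoriskError(
                f"shifted mean for {cpg} is {shifted:.3f}, outside (0, 1)"
            )
        means[status == 1, j] = shifted
    means = np.clip(means, 0.001, 0.999)
    values = rng.beta(means * precision, (1.0 - means) * precision)
    return MethylationMatrix(samples=list(cohort.index), cpg_ids=cpg_ids, values=values)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    effects: EffectSpec,
    exposure_probs: tuple[float, float, float] = (0.3, 0.4, 0.3),
    age_mean: float = 65.0,
    age_sd: float = 11.0,
    male_fraction: float = 0.71,
    exposure_missing_fraction: float = 0.0,
    exposure_missing_in: str = "cases",
    seed: int = 0,
) -> pd.DataFrame:
    """Assign exposure/age/sex and draw case status from the logistic model.

    Disease probability per sample is
    ``expit(alpha + sum beta_m dose_m + gamma_exposure + gxe + age + sex)``
    with age centred at ``age_mean``.  A configurable fraction of exposure
    values is then set missing (by default among cases only, mirroring a
    retrospective design where exposure histories of some cases are lost).
    """
    probs = np.asarray(exposure_probs, dtype=float)
    if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise MesoriskError("exposure_probs must be a 3-vector summing to 1")
    unknown = [v for v in effects.causal_variants if v not in genotypes.variant_ids]
    unknown += [g[0] for g in effects.gxe_terms if g[0] not in genotypes.variant_ids]
    if unknown:
        raise MesoriskError(f"unknown causal variant ids: {sorted(set(unknown))[:5]}")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    exposure = rng.choice(np.array([0, 1, 2]), size=n, p=probs)
    age = rng.normal(age_mean, age_sd, size=n)
    sex = np.where(rng.random(n) < male_fraction, "M", "F")

    lp = np.full(n, effects.baseline_logit, dtype=float)
    for vid, beta in effects.causal_variants.items():
        dose = genotypes.dosages[:, genotypes.variant_ids.get_loc(vid)]
        lp += beta * np.nan_to_num(dose, nan=0.0)
    low_or, high_or = effects.exposure_log_ors
    lp += np.where(exposure == 1, low_or, 0.0) + np.where(exposure == 2, high_or, 0.0)
    for vid, level, g in effects.gxe_terms:
        dose = genotypes.dosages[:, genotypes.variant_ids.get_loc(vid)]
        lp += g * np.nan_to_num(dose, nan=0.0) * (exposure == level)
    lp += effects.age_log_or * (age - age_mean)
    lp += effects.sex_log_or * (sex == "M")
    status = (rng.random(n) < expit(lp)).astype(int)

    exposure = pd.array(exposure, dtype="Int64")
    if exposure_missing_fraction > 0:
        pool = np.flatnonzero(status == 1) if exposure_missing_in == "cases" else np.arange(n)
        n_miss = int(round(exposure_missing_fraction * len(pool)))
        miss = rng.choice(pool, size=min(n_miss, len(pool)), replace=False)
        exposure[miss] = pd.NA
    cohort = pd.DataFrame(
        {
            "status": status,
            "age": np.round(age, 2),
            "sex": sex,
            "exposure": exposure,
        },
        index=pd.Index(genotypes.samples, name="sample_id"),
    )
    return cohort


def sample_case_control(
    population: PopulationSample,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> PopulationSample:
    """Uniform subsample without replacement within each status stratum."""
    rng = np.random.default_rng(seed)
    status = population.cohort["status"].to_numpy(dtype=int)
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    if len(case_idx) < n_cases:
        raise MesoriskError(
            f"requested {n_cases} cases but only {len(case_idx)} available "
            f"(short by {n_cases - len(case_idx)})"
        )
    if len(ctrl_idx) < n_controls:
        raise MesoriskError(
            f"requested {n_controls} controls but only {len(ctrl_idx)} available "
            f"(short by {n_controls - len(ctrl_idx)})"
        )
    if n_controls == 0:
        logger.warning("sample_case_control: 0 controls requested; cases-only sample")
    take = np.concatenate(
        [
            np.sort(rng.choice(case_idx, size=n_cases, replace=False)),
            np.sort(rng.choice(ctrl_idx, size=n_controls, replace=False)),
        ]
    )
    return population.subset(take)


def sample_matched_nested(
    population: PopulationSample,
    age_caliper: float = 1.5,
    seed: int = 0,
) -> PopulationSample:
    """1:1 match every case to a control of identical sex and exposure level
    with |age difference| <= ``age_caliper``.

    Greedy in ascending order of case age; within a case, the nearest-age
    eligible control wins (exact-distance ties broken by a seeded shuffle).
    Unmatched cases are dropped with a logged count.  Cases with missing
    exposure cannot be matched on exposure and are dropped.
    """
    cohort = population.cohort
    status = cohort["status"].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    cases = cohort.index[status == 1]
    controls = cohort.index[status == 0]
    if len(cases) == 0 or len(controls) == 0:
        logger.warning("sample_matched_nested: no cases or no controls; empty matched set")
        return population.subset(np.array([], dtype=int), pairs=pd.DataFrame(
            columns=["pair_id", "case_id", "control_id", "age_diff"]))

    ctrl = cohort.loc[controls, ["age", "sex", "exposure"]].copy()
    available = set(controls)
    order = cohort.loc[cases].sort_values("age", kind="stable").index
    pairs = []
    n_unmatched = 0
    for case_id in order:
        row = cohort.loc[case_id]
        if pd.isna(row["exposure"]):
            n_unmatched += 1
            continue
        eligible = ctrl.index[
            (ctrl["sex"] == row["sex"])
            & (ctrl["exposure"] == row["exposure"])
            & ((ctrl["age"] - row["age"]).abs() <= age_caliper)
            & pd.Index(ctrl.index).isin(available)
        ]
        if len(eligible) == 0:
            n_unmatched += 1
            continue
        dist = (ctrl.loc[eligible, "age"] - row["age"]).abs().to_numpy()
        shuffled = rng.permutation(len(eligible))  # exact-distance ties resolve randomly
        best = eligible[shuffled][np.argsort(dist[shuffled], kind="stable")[0]]
        available.discard(best)
        pairs.append(
            {
                "pair_id": len(pairs),
                "case_id": case_id,
                "control_id": best,
                "age_diff": float(abs(cohort.loc[best, "age"] - row["age"])),
            }
        )
    if n_unmatched:
        logger.info("sample_matched_nested: %d cases unmatched and dropped", n_unmatched)
    pairs_df = pd.DataFrame(pairs, columns=["pair_id", "case_id", "control_id", "age_diff"])
    if pairs_df.empty:
        logger.warning("sample_matched_nested: empty matched set")
        return population.subset(np.array([], dtype=int), pairs=pairs_df)
    take_ids: list = []
    for _, p in pairs_df.iterrows():
        take_ids.extend([p["case_id"], p["control_id"]])
    pos = pd.Index(cohort.index).get_indexer(pd.Index(take_ids))
    return population.subset(pos, pairs=pairs_df)
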