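"""Shared in-memory containers for the pipeline.

Genotypes, methylation and cohort data travel together through every stage;
the invariant maintained everywhere is that the three tables index the same
samples in the same order.  Sample subsetting therefore only happens through
:meth:`PopulationSample.subset`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a cohort table (``sample_id`` is the index).
COHORT_COLUMNS = ("status", "age", "sex", "exposure")

#: Required columns of a summary-statistics table (GWAS-SSF-like naming).
SUMSTATS_COLUMNS = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
    "effect_allele_frequency",
    "n",
)

#: Required columns of variant metadata inside a :class:`GenotypeMatrix`.
VARIANT_COLUMNS = ("chromosome", "position", "ref", "alt")


class MesoriskError(ValueError):
    """Base error for invalid inputs anywhere in the pipeline."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``dosages``.
    variants
        Metadata frame indexed by variant id with columns
        ``chromosome, position (1-based), ref, alt``.
    dosages
        Float array of shape ``(n_samples, n_variants)``; alt-allele dose in
        ``[0, 2]``, ``NaN`` for missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise MesoriskError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise MesoriskError(f"variant metadata missing columns: {missing}")
        if self.variants.index.has_duplicates:
            dup = self.variants.index[self.variants.index.duplicated()][:5]
            raise MesoriskError(f"duplicate variant ids: {list(dup)}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise MesoriskError("dosages must lie in [0, 2] or be missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant (combined sample, missing skipped)."""
        af = self.alt_allele_frequency()
        return pd.Series(np.minimum(af, 1.0 - af), index=self.variants.index, name="maf")

    def alt_allele_frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, order: np.ndarray) -> "GenotypeMatrix":
        """Row subset/reorder by positional index."""
        order = np.asarray(order)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in order],
            variants=self.variants,
            dosages=self.dosages[order],
        )

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = self.variants.index.get_indexer(pd.Index(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0][:5]
            raise MesoriskError(f"variants not present: {missing}")
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx],
            dosages=self.dosages[:, idx],
        )


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta-value matrix; beta-values live in [0, 1]."""

    samples: list[str]
    cpg_ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.cpg_ids = pd.Index(self.cpg_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.cpg_ids)):
            raise MesoriskError(
                f"methylation shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.cpg_ids)} CpGs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            raise MesoriskError("beta-values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def subset_samples(self, order: np.ndarray) -> "MethylationMatrix":
        order = np.asarray(order)
        return MethylationMatrix(
            samples=[self.samples[i] for i in order],
            cpg_ids=self.cpg_ids,
            values=self.values[order],
        )


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table: index = sample id; status in {0,1}; sex in {F,M};
    exposure in {0,1,2} or missing."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise MesoriskError(f"cohort table missing columns: {missing}")
    if cohort.index.has_duplicates:
        raise MesoriskError("duplicate sample ids in cohort table")
    if not set(pd.unique(cohort["status"])) <= {0, 1}:
        raise MesoriskError("status must be binary 0/1")
    if not set(pd.unique(cohort["sex"].dropna())) <= {"F", "M"}:
        raise MesoriskError("sex must be coded F/M")
    expo = pd.to_numeric(cohort["exposure"], errors="coerce")
    known = expo.dropna()
    if not set(known.unique()) <= {0, 1, 2}:
        bad = sorted(set(known.unique()) - {0, 1, 2})
        raise MesoriskError(f"unknown exposure codes: {bad}")
    return cohort


@dataclass
class RiskScoreSet:
    """Per-sample risk scores plus provenance of the features that built them.

    ``features`` records (identifier, weight, effect allele or CpG) so a score
    can be re-derived or transported to another dataset.
    """

    scores: pd.Series
    features: pd.DataFrame
    name: str = "score"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise MesoriskError("scores must be finite")

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class PopulationSample:
    """A cohort with aligned genotype / methylation / phenotype tables."""

    genotypes: GenotypeMatrix
    cohort: pd.DataFrame
    methylation: MethylationMatrix | None = None
    pairs: pd.DataFrame | None = field(default=None)  # matched-design pairing, if any

    def __post_init__(self) -> None:
        validate_cohort(self.cohort)
        ids = list(self.cohort.index)
        if self.genotypes.samples != ids:
            raise MesoriskError("genotype and cohort sample ids differ (or out of order)")
        if self.methylation is not None and self.methylation.samples != ids:
            raise MesoriskError("methylation and cohort sample ids differ (or out of order)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cohort.index)

    @property
    def n_samples(self) -> int:
        return len(self.cohort)

    def subset(self, order: np.ndarray, pairs: pd.DataFrame | None = None) -> "PopulationSample":
        """Positional subset applied consistently to every component."""
        order = np.asarray(order)
        return PopulationSample(
            genotypes=self.genotypes.subset_samples(order),
            cohort=self.cohort.iloc[order],
            methylation=None if self.methylation is None else self.methylation.subset_samples(order),
            pairs=pairs,
        )

    def subset_ids(self, ids) -> "PopulationSample":
        pos = pd.Index(self.cohort.index).get_indexer(pd.Index(ids))
        if (pos < 0).any():
            raise MesoriskError("subset ids not all present in population")
        return self.subset(pos)


def validate_summary_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Check summary-statistics invariants (se > 0, p in (0,1], unique ids)."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in table.columns]
    if missing:
        raise MesoriskError(f"summary statistics missing columns: {missing}")
    if table["variant_id"].duplicated().any():
        raise MesoriskError("duplicate variant ids in summary statistics")
    if (table["standard_error"] <= 0).any():
        raise MesoriskError("standard_error must be positive")
    p = table["p_value"]
    if ((p <= 0) | (p > 1)).any():
        raise MesoriskError("p_value must lie in (0, 1]")
    return table


def replace_dataclass(obj, **changes):
    return dataclasses.replace(obj, **changes)
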