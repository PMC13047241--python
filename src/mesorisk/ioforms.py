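"""Readers and writers for the plain-text formats the pipeline touches.

VCF v4.2 for genotypes (via cyvcf2), tab-separated text for everything else
(GWAS-SSF-like summary statistics, methylation beta-value matrices, cohort
tables, risk scores).  Conventions: coordinates are 1-based throughout, TSV
is UTF-8, '.' or 'NA' are accepted as missing on read and 'NA' is written.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    GenotypeMatrix,
    MesoriskError,
    MethylationMatrix,
    RiskScoreSet,
    SUMSTATS_COLUMNS,
    validate_cohort,
    validate_summary_stats,
)

logger = logging.getLogger("mesorisk")

_MISSING_TOKENS = ("NA", ".")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Parse a VCF v4.2 into a dosage matrix.

    Dosage is the DS field when present, else the alt-allele count from GT;
    missing GT becomes a missing dosage.  Multiallelic records are rejected
    (the pipeline expects biallelic, normalized input).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows, cols = [], []
    for k, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise MesoriskError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} (record {k}); "
                "split into biallelic records first"
            )
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = rec.genotype.array()  # (n, ploidy+1); -1 = missing allele
            alleles = gts[:, :2]
            dose = np.where(
                (alleles < 0).any(axis=1), np.nan, (alleles == 1).sum(axis=1)
            ).astype(float)
        cols.append(dose)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0]}"
        meta_rows.append(
            {
                "variant_id": vid,
                "chromosome": rec.CHROM,
                "position": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    if not meta_rows:
        raise MesoriskError(f"no records in VCF {path}")
    variants = pd.DataFrame(meta_rows).set_index("variant_id")
    return GenotypeMatrix(samples=samples, variants=variants, dosages=np.column_stack(cols))


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2.

    Integral dosages round-trip as GT allele counts; when any dosage is
    non-integral a DS field is added so ``read_vcf`` reproduces dosages
    exactly.
    """
    d = genotypes.dosages
    called = d[~np.isnan(d)]
    integral = called.size == 0 or bool(np.all(np.mod(called, 1) == 0))
    fmt = "GT" if integral else "GT:DS"
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not integral:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        chroms = pd.unique(genotypes.variants["chromosome"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        order = np.lexsort(
            (genotypes.variants["position"].to_numpy(), genotypes.variants["chromosome"].to_numpy())
        )
        for j in order:
            meta = genotypes.variants.iloc[j]
            fields = [
                str(meta["chromosome"]),
                str(int(meta["position"])),
                str(genotypes.variants.index[j]),
                str(meta["ref"]),
                str(meta["alt"]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            col = d[:, j]
            entries = []
            for v in col:
                if np.isnan(v):
                    entries.append("./." if integral else "./.:.")
                elif integral:
                    entries.append(gt_map[int(round(v))])
                else:
                    entries.append(f"{gt_map.get(int(round(v)), '0/1')}:{v:g}")
            fh.write("\t".join(fields + entries) + "\n")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class ReadAudit:
    n_read: int
    n_rejected: int


def read_summary_stats(path: str | os.PathLike) -> tuple[pd.DataFrame, ReadAudit]:
    """Read a GWAS-SSF-like TSV; rows violating se > 0 or p in (0,1] are
    rejected and counted in the returned audit."""
    table = pd.read_csv(path, sep="\t", na_values=list(_MISSING_TOKENS))
    missing = [c for c in SUMSTATS_COLUMNS if c not in table.columns]
    if missing:
        raise MesoriskError(f"summary statistics file missing column(s): {missing}")
    ok = (table["standard_error"] > 0) & (table["p_value"] > 0) & (table["p_value"] <= 1)
    n_rej = int((~ok).sum())
    if n_rej:
        logger.warning("read_summary_stats: rejected %d invalid rows", n_rej)
    table = table.loc[ok].reset_index(drop=True)
    validate_summary_stats(table)
    return table, ReadAudit(n_read=len(table), n_rejected=n_rej)


def write_summary_stats(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_summary_stats(table)
    out = table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


# ---------------------------------------------------------------------------
# Methylation / cohort / scores
# ---------------------------------------------------------------------------

def read_methylation(path: str | os.PathLike) -> MethylationMatrix:
    """Read a CpG-by-sample beta-value TSV (rows = CpGs, columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(_MISSING_TOKENS))
    values = df.to_numpy(dtype=float).T
    with np.errstate(invalid="ignore"):
        if np.nanmin(values) < 0 or np.nanmax(values) > 1:
            raise MesoriskError("beta-values outside [0, 1] in methylation file")
    return MethylationMatrix(samples=list(df.columns), cpg_ids=df.index, values=values)


def write_methylation(matrix: MethylationMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(matrix.values.T, index=matrix.cpg_ids, columns=matrix.samples)
    df.index.name = "cpg_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort TSV (sample_id, status{0,1}, age, sex{F,M}, exposure{0,1,2,NA})."""
    df = pd.read_csv(
        path, sep="\t", na_values=list(_MISSING_TOKENS), dtype={"sex": "string"}
    )
    if "sample_id" not in df.columns:
        raise MesoriskError("cohort file must have a sample_id column")
    df = df.set_index("sample_id")
    df["exposure"] = pd.array(
        pd.to_numeric(df["exposure"], errors="raise"), dtype="Int64"
    )
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_cohort(cohort)
    out = cohort.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def write_scores(scores: RiskScoreSet, path: str | os.PathLike) -> None:
    out = scores.scores.rename(scores.name).to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_scores(path: str | os.PathLike, name: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=list(_MISSING_TOKENS))
    col = name if name is not None else df.columns[0]
    return df[col]


def check_sample_concordance(*tables) -> None:
    """Raise listing discrepancies when sample sets differ across inputs."""
    sets = []
    for t in tables:
        if isinstance(t, GenotypeMatrix) or isinstance(t, MethylationMatrix):
            sets.append(set(t.samples))
        else:
            sets.append(set(t.index))
    base = sets[0]
    for s in sets[1:]:
        if s != base:
            only_a = sorted(base - s)[:5]
            only_b = sorted(s - base)[:5]
            raise MesoriskError(
                f"sample sets differ between inputs: only in first={only_a}, "
                f"only in other={only_b}"
            )
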