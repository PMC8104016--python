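"""Readers and writers for the tabular inputs of the pipeline.

Formats handled here: gene annotation (GTF via pyranges, or 6-column BED),
promoter/variant probe tables, peak tracks (BED3+), LD tables, SNP universe
tables, trait catalogs and expression matrices.  All genomic tables are
0-based half-open once in memory.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import Gene, GeneAnnotation, GenomicInterval

__all__ = [
    "read_gene_annotation",
    "genes_from_frame",
    "read_promoter_probes",
    "read_variant_probes",
    "read_peaks",
    "read_ld_table",
    "read_snp_universe",
    "read_trait_catalog",
    "read_expression",
    "write_expression",
]

PROMOTER_COLUMNS = ["gene_id", "chrom", "start", "end"]
VARIANT_COLUMNS = ["rsid", "chrom", "pos", "maf"]
LD_COLUMNS = ["lead_rsid", "proxy_rsid", "r2", "distance"]
UNIVERSE_COLUMNS = ["rsid", "chrom", "pos", "maf", "n_ld_buddies"]


def genes_from_frame(df: pd.DataFrame) -> GeneAnnotation:
    """Build a :class:`GeneAnnotation` from a frame with columns
    gene_id, name, chrom, start, end, strand (0-based half-open)."""
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        tss = body.start if row.strand == "+" else body.end - 1
        genes.append(Gene(row.gene_id, getattr(row, "name", row.gene_id), tss, row.strand, body))
    return GeneAnnotation(genes)


def read_gene_annotation(path: str) -> GeneAnnotation:
    """Read genes from a GTF (``gene`` features) or a 6-column BED file."""
    if str(path).endswith((".gtf", ".gtf.gz")):
        import pyranges

        df = pyranges.read_gtf(path).df
        df = df[df["Feature"] == "gene"]
        name_col = "gene_name" if "gene_name" in df.columns else "gene_id"
        frame = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "name": df[name_col],
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"],
                "end": df["End"],
                "strand": df["Strand"],
            }
        )
    else:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            comment="#",
        )
        frame["name"] = frame["gene_id"]
    return genes_from_frame(frame)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def read_promoter_probes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PROMOTER_COLUMNS, "promoter probe table")
    return df[PROMOTER_COLUMNS].copy()


def read_variant_probes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, VARIANT_COLUMNS, "variant probe table")
    return df[VARIANT_COLUMNS].copy()


def read_peaks(path: str) -> pd.DataFrame:
    """BED3+ peak track; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def read_ld_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, LD_COLUMNS, "LD table")
    bad = df[(df["r2"] < 0) | (df["r2"] > 1)]
    if len(bad):
        raise ValueError(f"LD table: {len(bad)} rows with r2 outside [0, 1]")
    return df[LD_COLUMNS].copy()


def read_snp_universe(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, UNIVERSE_COLUMNS, "SNP universe table")
    return df[UNIVERSE_COLUMNS].copy()


def read_trait_catalog(path: str) -> pd.DataFrame:
    """Trait catalog TSV: rsid, trait, pvalue (association p <= 1e-6)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["rsid", "trait", "pvalue"], "trait catalog")
    over = df[df["pvalue"] > 1e-6]
    if len(over):
        warnings.warn(
            f"trait catalog: {len(over)} associations with p > 1e-6 "
            "(catalog is expected to be pre-filtered)"
        )
    return df[["rsid", "trait", "pvalue"]].copy()


def read_expression(path: str) -> pd.DataFrame:
    """Expression matrix TSV: gene_id index, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.shape[1] < 1:
        raise ValueError("expression matrix has no sample columns")
    return df


def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
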