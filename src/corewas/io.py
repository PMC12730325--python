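"""Readers and writers for the tabular interchange formats.

TSV is the canonical interchange (the biobank summary-statistic
convention); gzip is handled transparently by extension.  Column dialects
map cohort-specific headers (e.g. FinnGen-style ``#chrom``/``sebeta``/
``pval``) onto the package's canonical names.  Genotypes are read from a
variant x individual allele-count TSV or from a VCF (GT field, via pysam).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DIALECTS",
    "read_summary_stats",
    "write_summary_stats",
    "read_bed",
    "write_bed",
    "read_pip_table",
    "read_phenotype_covariates",
    "read_variant_scores",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
]

MANDATORY = ("chrom", "pos", "ref", "alt", "af", "beta", "se", "p")

DIALECTS: dict[str, dict[str, str]] = {
    "generic": {},
    "finngen": {"#chrom": "chrom", "sebeta": "se", "pval": "p", "af_alt": "af"},
    "mvp": {"chromosome": "chrom", "position": "pos", "effect": "beta",
            "stderr": "se", "pvalue": "p", "freq": "af"},
}


def read_summary_stats(path, dialect="generic") -> pd.DataFrame:
    """Read and validate a summary-statistic table.

    ``dialect`` is a named column map or a custom ``{file_col: canon_col}``
    dict.  Rows with out-of-range values (af outside (0,1), se <= 0,
    p outside (0,1]) are dropped, logged, and counted in
    ``df.attrs["n_rejected"]``.  A missing mandatory column is a hard
    error naming the column.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns=mapping)
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    for col in MANDATORY:
        if col not in df.columns:
            raise ValueError(f"summary-stat file {path} is missing mandatory column {col!r}")
    ok = (
        df["af"].between(0, 1, inclusive="neither")
        & (df["se"] > 0)
        & df["p"].between(0, 1, inclusive="right")
        & df["pos"].notna()
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d malformed rows", path, n_rejected)
    out = df[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED4 gene intervals: chrom, start, end, gene (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str})
    bad = df["end"] <= df["start"]
    if bad.any():
        logger.warning("%s: skipping %d malformed intervals", path, int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return df


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_pip_table(path) -> pd.DataFrame:
    """Fine-mapping PIP table: locus, chrom, pos, ref, alt, pip."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "locus": str})
    for col in ("locus", "chrom", "pos", "ref", "alt", "pip"):
        if col not in df.columns:
            raise ValueError(f"PIP table {path} is missing mandatory column {col!r}")
    return df


def read_phenotype_covariates(path, phenotype_col: str = "phenotype"):
    """Phenotype + covariate TSV -> (phenotype array, covariate frame)."""
    df = pd.read_csv(path, sep="\t")
    if phenotype_col not in df.columns:
        raise ValueError(f"{path} is missing phenotype column {phenotype_col!r}")
    y = df[phenotype_col].to_numpy()
    covars = df.drop(columns=[phenotype_col])
    return y, covars


def read_variant_scores(path) -> pd.DataFrame:
    """Variant functional-effect scores: variant_id, gene, score in [0,1]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "gene", "score"):
        if col not in df.columns:
            raise ValueError(f"score table {path} is missing mandatory column {col!r}")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("variant scores must lie in [0, 1]")
    return df


def read_genotypes(path):
    """Read genotypes as (variant table, alt-allele count matrix).

    ``.vcf``/``.vcf.gz`` files go through pysam's GT parsing; anything else
    is treated as a TSV with columns variant_id, chrom, pos, ref, alt and
    one integer column per individual.
    """
    path = Path(path)
    if path.name.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in ("variant_id", "chrom", "pos", "ref", "alt") if c in df.columns]
    if "variant_id" not in meta_cols:
        raise ValueError(f"genotype TSV {path} is missing mandatory column 'variant_id'")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    G = df[sample_cols].to_numpy(dtype=np.int8)
    return df[meta_cols], G


def _read_vcf(path):
    import pysam

    variants = []
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            variants.append({
                "variant_id": f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}",
                "chrom": str(rec.chrom), "pos": rec.pos, "ref": rec.ref, "alt": alt,
            })
            rows.append([sum(1 for a in rec.samples[s]["GT"] if a) for s in samples])
    return pd.DataFrame(variants), np.asarray(rows, dtype=np.int8)


def write_genotypes_tsv(variants: pd.DataFrame, G: np.ndarray, path,
                        sample_prefix: str = "ind") -> None:
    meta = variants[["variant_id", "chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    calls = pd.DataFrame(G, columns=[f"{sample_prefix}{j:05d}" for j in range(G.shape[1])])
    pd.concat([meta, calls], axis=1).to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(variants: pd.DataFrame, G: np.ndarray, path,
                        sample_prefix: str = "ind") -> None:
    """Minimal VCFv4.2 with unphased GT, re-readable by pysam."""
    samples = [f"{sample_prefix}{j:05d}" for j in range(G.shape[1])]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, row in enumerate(variants.itertuples(index=False)):
            calls = "\t".join(gt[int(g)] for g in G[i])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t{calls}\n")
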