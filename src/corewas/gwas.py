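"""Variant-to-gene mapping, gene-coherence filters and GWAS QC.

Single-variant GWAS hits are noisy at the gene level: many significant
variants are intergenic, many genes are supported by exactly one variant,
and direction of effect can conflict between variants of the same gene.
This module implements the coherence filters that demote such genes --
minor-allele-frequency filtering, a >= 2-variant same-direction rule --
plus the routine QC statistics (genomic-inflation factor with QQ
coordinates, and a variance-inflation-factor screen for covariate
collinearity).

Coordinate conventions: gene intervals are BED-style 0-based half-open on
disk; summary-statistic positions are 1-based.  Conversion happens here,
at the mapping boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InflationReport",
    "map_variants_to_genes",
    "filter_maf",
    "gene_coherence_filter",
    "genomic_inflation",
    "vif_screen",
    "GENOME_WIDE_P",
    "EXOME_SCALE_P",
]

#: conventional genome-wide and exome-scale significance thresholds
GENOME_WIDE_P = 5e-8
EXOME_SCALE_P = 5e-7

#: null median of the 1-df chi-square distribution
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})


def _build_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end <= start:
            logger.warning("skipping malformed interval %s:%s-%s (%s)",
                           row.chrom, row.start, row.end, row.gene)
            continue
        trees.setdefault(str(row.chrom), IntervalTree()).addi(start, end, row.gene)
    return trees


def map_variants_to_genes(records: pd.DataFrame, genes: pd.DataFrame,
                          coding_only: bool = False,
                          exclude_sex_chroms: bool | None = None,
                          padding: int = 0) -> pd.DataFrame:
    """Annotate summary-stat records with all overlapping genes.

    ``genes`` carries BED-style 0-based half-open ``start``/``end``;
    ``records.pos`` is 1-based, so position ``pos`` overlaps interval
    ``[start, end)`` iff ``start <= pos - 1 < end``.  A variant inside two
    nested genes yields two output rows.  Intergenic records get
    ``gene = NA``; with ``coding_only=True`` (gene-restricted mode) they
    are dropped, and sex chromosomes are excluded by default.
    ``padding`` extends every interval by +-bp.
    """
    if exclude_sex_chroms is None:
        exclude_sex_chroms = coding_only
    trees = _build_trees(genes)
    rows = []
    for i, row in enumerate(records.itertuples(index=False)):
        chrom = str(row.chrom)
        if exclude_sex_chroms and chrom in SEX_CHROMS:
            continue
        hits = trees.get(chrom, IntervalTree()).overlap(
            int(row.pos) - 1 - padding, int(row.pos) + padding) if chrom in trees else []
        if hits:
            for hit in sorted(hits, key=lambda h: str(h.data)):
                rows.append((i, hit.data))
        else:
            rows.append((i, None))
    out = records.reset_index(drop=True)
    ann = pd.DataFrame(rows, columns=["_row", "gene"])
    out = out.merge(ann, left_index=True, right_on="_row").drop(columns="_row")
    out = out.reset_index(drop=True)
    if coding_only:
        out = out[out["gene"].notna()].reset_index(drop=True)
    return out


def filter_maf(records: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep records with minor allele frequency ``min(af, 1-af)`` above threshold."""
    maf = np.minimum(records["af"], 1.0 - records["af"])
    return records[maf > threshold].reset_index(drop=True)


def gene_coherence_filter(records: pd.DataFrame, min_variants: int = 2,
                          coherence: float = 0.75) -> pd.DataFrame:
    """Per-gene support from significant, gene-annotated records.

    For each gene: the number of supporting variants, the fraction sharing
    the modal beta sign (``direction_coherence``), and a ``passes`` flag
    requiring at least ``min_variants`` variants and coherence at or above
    the threshold.  Genes supported by a single variant never pass.
    """
    ann = records[records["gene"].notna()]
    rows = []
    for gene, grp in ann.groupby("gene", sort=True):
        signs = np.sign(grp["beta"].to_numpy())
        n = len(grp)
        n_pos = int((signs > 0).sum())
        n_neg = int((signs < 0).sum())
        frac = max(n_pos, n_neg) / max(n_pos + n_neg, 1)
        rows.append({
            "gene": gene,
            "n_sig_variants": n,
            "direction_coherence": frac,
            "passes": (n >= min_variants) and (frac >= coherence),
        })
    return pd.DataFrame(rows, columns=["gene", "n_sig_variants",
                                       "direction_coherence", "passes"])


@dataclass
class InflationReport:
    """Genomic-inflation factor and QQ-plot coordinates."""

    lambda_gc: float
    qq: pd.DataFrame  # columns: expected, observed (-log10 p, ascending)


def genomic_inflation(pvalues) -> InflationReport:
    """Median-based genomic-inflation factor lambda_GC.

    ``lambda = median(chi2_obs) / median(chi2_null)`` where each p-value is
    converted back to its 1-df chi-square quantile and the null median is
    0.4549.  Under a well-calibrated null lambda is approximately 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_inflation requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_NULL_MEDIAN)
    obs = np.sort(-np.log10(p))
    exp = -np.log10((np.arange(p.size, 0, -1) - 0.5) / p.size)
    qq = pd.DataFrame({"expected": exp, "observed": obs})
    return InflationReport(lambda_gc=lam, qq=qq)


def vif_screen(covariates: pd.DataFrame, flags: tuple[float, float] = (5.0, 50.0)) -> pd.DataFrame:
    """Variance-inflation factor per covariate.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing covariate j (plus an
    intercept) on all the others.  Perfect collinearity yields ``inf``.
    Flag columns mark the conventional screening threshold (default 5) and
    the extreme threshold (default 50).
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("vif_screen needs at least two covariates")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) \
        else [f"x{j}" for j in range(X.shape[1])]
    rows = []
    for j in range(X.shape[1]):
        yj = X[:, j]
        others = np.column_stack([np.ones(X.shape[0]), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss == 0:
            vif = np.inf  # constant column: undefined, treat as flagged
        else:
            r2 = 1.0 - np.sum(resid**2) / tss
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": names[j], "vif": vif,
                     f"above_{flags[0]:g}": vif > flags[0],
                     f"above_{flags[1]:g}": vif > flags[1]})
    return pd.DataFrame(rows)
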