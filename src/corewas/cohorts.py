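"""Cross-cohort harmonisation and concordance of variant-level results.

Disjoint cohorts are compared by replication, never meta-analysed: variants
are matched by exact chrom:pos:ref:alt key (with a single ref/alt-swap rule
that negates beta and complements AF), missingness per cohort is reported,
and concordance of allele frequencies and effect directions -- including
discordant-direction flags at moderate effect size -- is summarised.
Strand-ambiguous variants (A/T, C/G) are never allele-flipped by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchReport",
    "ConcordanceReport",
    "match_variants",
    "flip_record",
    "concordance_report",
    "pleiotropy_profile",
]

STRAND_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_STAT_COLS = ("af", "beta", "se", "p")


def _key(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
            + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str))


def _flip_key(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
            + ":" + df["alt"].astype(str) + ":" + df["ref"].astype(str))


def flip_record(beta: float, af: float) -> tuple[float, float]:
    """Re-express a record on the swapped ref/alt allele (an involution)."""
    return -beta, 1.0 - af


@dataclass
class MatchReport:
    matches: pd.DataFrame
    missing_from_b: float       # fraction of A variants with no usable match in B
    missing_from_a: float       # fraction of B variants never matched
    n_flipped: int
    n_ambiguous: int            # excluded: both direct and swapped key present
    n_strand_ambiguous: int     # excluded: flip needed but alleles A/T or C/G


def match_variants(a: pd.DataFrame, b: pd.DataFrame,
                   allow_ambiguous_flip: bool = False) -> MatchReport:
    """Join two summary-stat tables on chrom:pos:ref:alt.

    Records absent under the direct key are retried with ref/alt swapped;
    a swap match records cohort B's beta negated and AF complemented, with
    ``flip_applied=True``.  If *both* the direct and the swapped key exist
    in B the match is ambiguous and excluded.  Strand-ambiguous allele
    pairs are never flipped unless ``allow_ambiguous_flip``.
    """
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    akey = _key(a)
    bkey = _key(b)
    if akey.duplicated().any() or bkey.duplicated().any():
        raise ValueError("duplicate variant keys within a cohort table")
    b_lookup = dict(zip(bkey, b.index))

    rows = []
    matched_b: set[int] = set()
    n_flip = n_amb = n_strand = 0
    aflip = _flip_key(a)
    for i in range(len(a)):
        direct = b_lookup.get(akey.iloc[i])
        swapped = b_lookup.get(aflip.iloc[i])
        if direct is not None and swapped is not None:
            n_amb += 1
            continue
        if direct is not None:
            rows.append((i, direct, False))
            matched_b.add(direct)
            continue
        if swapped is not None:
            pair = (str(a["ref"].iloc[i]), str(a["alt"].iloc[i]))
            if pair in STRAND_AMBIGUOUS and not allow_ambiguous_flip:
                n_strand += 1
                continue
            rows.append((i, swapped, True))
            matched_b.add(swapped)
            n_flip += 1

    out_rows = []
    for i, j, flipped in rows:
        rec = {"variant": akey.iloc[i], "flip_applied": flipped}
        for col in _STAT_COLS:
            rec[f"{col}_a"] = a[col].iloc[i] if col in a else np.nan
            v = b[col].iloc[j] if col in b else np.nan
            if flipped and col == "beta":
                v = -v
            if flipped and col == "af":
                v = 1.0 - v
            rec[f"{col}_b"] = v
        out_rows.append(rec)
    matches = pd.DataFrame(out_rows, columns=["variant", "flip_applied"]
                           + [f"{c}_{s}" for c in _STAT_COLS for s in ("a", "b")])
    return MatchReport(
        matches=matches,
        missing_from_b=1.0 - len(matches) / len(a) if len(a) else 0.0,
        missing_from_a=1.0 - len(matched_b) / len(b) if len(b) else 0.0,
        n_flipped=n_flip, n_ambiguous=n_amb, n_strand_ambiguous=n_strand,
    )


@dataclass
class ConcordanceReport:
    n_matches: int
    sign_concordance: float            # fraction of matches with agreeing beta sign
    sign_concordance_significant: float  # same, among pairs significant in both cohorts
    n_significant_pairs: int
    moderate_fraction: float           # fraction of cohort-A betas with |beta| > moderate
    discordant: pd.DataFrame           # opposite signs, both |beta| > moderate
    af_scatter: pd.DataFrame           # af_a, af_b for all matches
    af_scatter_rare: pd.DataFrame      # restricted to the rare-AF window


def concordance_report(matches: pd.DataFrame, moderate_beta: float = 0.1,
                       rare_bounds: tuple[float, float] = (0.001, 0.1),
                       sig_threshold: float = 1e-4) -> ConcordanceReport:
    """AF and effect-direction concordance between two matched cohorts."""
    if len(matches) == 0:
        raise ValueError("concordance_report requires at least one match")
    m = matches.dropna(subset=["beta_a", "beta_b"])
    agree = np.sign(m["beta_a"]) == np.sign(m["beta_b"])
    sig = (m["p_a"] < sig_threshold) & (m["p_b"] < sig_threshold)
    disc = m[~agree & (m["beta_a"].abs() > moderate_beta)
             & (m["beta_b"].abs() > moderate_beta)]
    lo, hi = rare_bounds
    af = matches[["variant", "af_a", "af_b"]].dropna()
    rare = af[(af["af_a"].between(lo, hi)) & (af["af_b"].between(lo, hi))]
    return ConcordanceReport(
        n_matches=len(matches),
        sign_concordance=float(agree.mean()) if len(m) else np.nan,
        sign_concordance_significant=float(agree[sig].mean()) if sig.any() else np.nan,
        n_significant_pairs=int(sig.sum()),
        moderate_fraction=float((m["beta_a"].abs() > moderate_beta).mean()) if len(m) else np.nan,
        discordant=disc.reset_index(drop=True),
        af_scatter=af.reset_index(drop=True),
        af_scatter_rare=rare.reset_index(drop=True),
    )


def pleiotropy_profile(phewas: pd.DataFrame, variant: str,
                       sig: float = 5e-8) -> pd.DataFrame:
    """Per-trait summary of one variant's phenome-wide associations.

    Returns the traits passing the significance threshold, partitioned by
    effect direction (positive beta = risk, negative = protective), with
    case counts.  An empty frame means no significant trait.
    """
    sub = phewas[phewas["variant"] == variant]
    sub = sub[sub["p"] < sig].copy()
    sub["direction"] = np.where(sub["beta"] > 0, "risk", "protective")
    cols = ["trait", "beta", "p", "direction"]
    if "n_cases" in sub.columns:
        cols.append("n_cases")
    return sub[cols].sort_values("p").reset_index(drop=True)
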