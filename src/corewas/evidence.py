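"""Multi-source evidence integration and core gene-list assembly.

Candidate predisposition genes accumulate evidence labels from the overlap
of independent sources (two FinnGen credible-set freezes, Open Targets
genetic-association tiers at GA >= 0.5 and >= 0.75, TWAS, PWAS,
ExPheWAS).  Genes whose *only* evidence is the unvalidated
OT0.75-and-TWAS combination (label ``b``) are excluded; the rest form the
high-confidence core list.  Supporting statistics: exact hypergeometric
set-overlap tests, exact binomial support tests, score-gap prioritisation
of Open Targets scores, and full Venn-region accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats

from corewas.datasets import parse_labels

__all__ = [
    "KNOWN_SOURCES",
    "LabelRule",
    "EvidenceConfig",
    "OverlapTest",
    "CoreGeneList",
    "default_config",
    "ot_threshold_filter",
    "score_gap_prioritize",
    "hypergeometric_overlap",
    "binomial_support_test",
    "assign_labels",
    "assemble_core",
    "venn_intersections",
]

KNOWN_SOURCES = frozenset(
    {"FG11", "FG12", "OT0.5", "OT0.75", "TWAS", "PWAS", "ExPheWAS"})

#: default background universe: the number of protein-coding genes the
#: gene-level analyses span
PROTEIN_CODING_UNIVERSE = 18_053


@dataclass(frozen=True)
class LabelRule:
    """A label applies when all of ``require`` and none of ``forbid`` hold."""

    require: frozenset
    forbid: frozenset = frozenset()

    def matches(self, memberships: frozenset) -> bool:
        return self.require <= memberships and not (self.forbid & memberships)


@dataclass
class EvidenceConfig:
    labels: dict[str, LabelRule]
    exclude_if_exactly: tuple[frozenset, ...] = (frozenset({"b"}),)
    ga_threshold: float = 0.5
    ga_high_threshold: float = 0.75
    known_sources: frozenset = KNOWN_SOURCES


def default_config() -> EvidenceConfig:
    """Label rules pinned by the published table footnotes.

    ``d`` = found in both FinnGen freezes, the high-confidence OT tier and
    TWAS; ``b`` = OT0.75 and TWAS without FinnGen support (the unvalidated
    combination); ``g`` = PWAS; ``i`` = ExPheWAS.  The remaining labels
    (a, c, e, f, h) are dataset-specific co-occurrence categories and must
    be supplied by the user's configuration.
    """
    return EvidenceConfig(labels={
        "d": LabelRule(frozenset({"FG11", "FG12", "OT0.75", "TWAS"})),
        "b": LabelRule(frozenset({"OT0.75", "TWAS"}),
                       forbid=frozenset({"FG11", "FG12"})),
        "g": LabelRule(frozenset({"PWAS"})),
        "i": LabelRule(frozenset({"ExPheWAS"})),
    })


def ot_threshold_filter(gene_table: pd.DataFrame, theta: float = 0.5,
                        score_col: str = "ga_score") -> pd.DataFrame:
    """Genes with genetic-association score at or above ``theta``."""
    scores = gene_table[score_col]
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return gene_table[scores >= theta].reset_index(drop=True)


def score_gap_prioritize(gene_table: pd.DataFrame, direction: str = "external-support",
                         top: int | None = None) -> pd.DataFrame:
    """Rank genes by the gap between their global and genetic scores.

    ``external-support``: genes whose global (all-evidence) score exceeds
    their genetic-association score rank first -- candidates backed by
    literature, models or constraint beyond GWAS.  ``genetic-only``: the
    converse, genes whose support is almost purely genetic.  Ties keep
    input order (stable sort).
    """
    df = gene_table.copy()
    gap = df["global_score"] - df["ga_score"]
    if direction == "external-support":
        df["score_gap"] = gap
    elif direction == "genetic-only":
        df["score_gap"] = -gap
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    df = df.sort_values("score_gap", ascending=False, kind="stable").reset_index(drop=True)
    return df.head(top) if top is not None else df


@dataclass
class OverlapTest:
    N: int
    K: int
    n: int
    k: int
    p_upper: float


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Exact upper-tail overlap probability P(X >= k), in log space.

    X counts the overlap of a fixed K-element set with an n-element draw
    (without replacement) from an N-element universe.  Terms are summed as
    log-binomials via log-gamma for numerical range.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"impossible overlap configuration N={N} K={K} n={n} k={k}")
    if k == 0:
        return OverlapTest(N, K, n, k, 1.0)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    j = np.arange(k, min(K, n) + 1)
    log_terms = log_comb(K, j) + log_comb(N - K, n - j) - log_comb(N, n)
    p = float(np.exp(logsumexp(log_terms)))
    return OverlapTest(N, K, n, k, min(p, 1.0))


def binomial_support_test(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0).

    The null proportion ``p0`` must be given explicitly: there is no
    universal background rate for literature support.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


def assign_labels(memberships, cfg: EvidenceConfig | None = None) -> frozenset:
    """Deterministic evidence labels for one gene's source memberships."""
    cfg = cfg or default_config()
    ms = frozenset(memberships)
    unknown = ms - cfg.known_sources
    if unknown:
        raise ValueError(f"unknown evidence sources: {sorted(unknown)}")
    return frozenset(lab for lab, rule in cfg.labels.items() if rule.matches(ms))


@dataclass
class CoreGeneList:
    table: pd.DataFrame          # gene, labels, core, exclusion_reason
    n_candidates: int
    n_multi_evidence: int
    n_excluded: int
    n_core: int

    @property
    def core_genes(self) -> list[str]:
        return self.table.loc[self.table["core"], "gene"].tolist()


def assemble_core(labelled: pd.DataFrame, cfg: EvidenceConfig | None = None,
                  label_col: str = "evidence") -> CoreGeneList:
    """Assemble the core gene list with the b-only exclusion rule.

    ``labelled`` needs a ``gene`` column and a label column (comma-joined
    string or set).  Duplicate genes are merged by label union, making the
    operation idempotent.  A gene is excluded iff its label set is exactly
    one of the disqualifying sets (default: ``{b}`` alone); any additional
    evidence keeps it in the core, so adding evidence never demotes a gene.
    """
    cfg = cfg or default_config()
    if len(labelled) == 0:
        empty = pd.DataFrame(columns=["gene", "labels", "core", "exclusion_reason"])
        return CoreGeneList(empty, 0, 0, 0, 0)
    merged: dict[str, frozenset] = {}
    for gene, value in zip(labelled["gene"], labelled[label_col]):
        merged[gene] = merged.get(gene, frozenset()) | parse_labels(value)
    rows = []
    for gene in sorted(merged):
        labels = merged[gene]
        excluded = labels in cfg.exclude_if_exactly
        rows.append({
            "gene": gene,
            "labels": ",".join(sorted(labels)),
            "core": not excluded,
            "exclusion_reason": (
                f"only unvalidated evidence {{{','.join(sorted(labels))}}}"
                if excluded else ""),
        })
    table = pd.DataFrame(rows)
    n_multi = sum(len(labels) >= 2 for labels in merged.values())
    n_excl = int((~table["core"]).sum())
    return CoreGeneList(table, n_candidates=len(merged), n_multi_evidence=n_multi,
                        n_excluded=n_excl, n_core=len(merged) - n_excl)


def venn_intersections(named_sets: dict[str, set]) -> pd.DataFrame:
    """All 2^m - 1 exclusive Venn regions with counts and member lists.

    Each region is the set of elements belonging to exactly the named
    combination; region counts therefore sum to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("venn_intersections needs at least two sets")
    names = list(named_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set.union(*(set(named_sets[n]) for n in names if n not in combo), set())
            members = sorted(inside - outside)
            rows.append({"region": "&".join(combo), "n_sets": r,
                         "count": len(members), "members": ",".join(map(str, members))})
    return pd.DataFrame(rows)
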