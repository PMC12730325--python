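"""95% credible sets from fine-mapping posterior inclusion probabilities.

Fine-mapping itself (Bayes factors, LD matrices) is upstream: PIPs arrive
as inputs.  A credible set at coverage ``target`` is the *smallest* set of
PIP-ranked variants whose cumulative PIP reaches the target; ties are
broken by position, then ref/alt allele, for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from corewas import gwas

__all__ = ["CredibleSet", "build_credible_set", "build_credible_sets", "cs_to_genes"]


@dataclass
class CredibleSet:
    locus_id: str
    members: pd.DataFrame      # rank, variant_id, chrom, pos, ref, alt, pip, cum_pip
    cumulative_pip: float
    target: float
    under_coverage: bool = False

    def __len__(self) -> int:
        return len(self.members)


def build_credible_set(locus: pd.DataFrame, target: float = 0.95,
                       locus_id: str | None = None) -> CredibleSet:
    """Minimal PIP-descending prefix with cumulative PIP >= ``target``.

    If the locus total PIP falls short of the target, all variants are
    returned with ``under_coverage=True``.  Duplicate variant ids are
    rejected.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("coverage target must lie in (0, 1]")
    df = locus.copy()
    pip = df["pip"].to_numpy(dtype=float)
    if np.any((pip < 0) | (pip > 1) | np.isnan(pip)):
        raise ValueError("PIPs must lie in [0, 1]")
    if "variant_id" not in df.columns:
        df["variant_id"] = [
            f"{c}:{p}:{r}:{a}" for c, p, r, a
            in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        ]
    if df["variant_id"].duplicated().any():
        dupes = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in locus: {dupes}")

    sort_cols = ["pip"] + [c for c in ("pos", "ref", "alt") if c in df.columns]
    df = df.sort_values(sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1),
                        kind="stable").reset_index(drop=True)
    cum = df["pip"].cumsum()
    reached = cum >= target - 1e-12
    if reached.any():
        k = int(np.argmax(reached.to_numpy())) + 1
        under = False
    else:
        k = len(df)
        under = True
    members = df.iloc[:k].copy()
    members.insert(0, "rank", np.arange(1, k + 1))
    members["cum_pip"] = cum.iloc[:k].to_numpy()
    lid = locus_id if locus_id is not None else str(
        df["locus"].iloc[0] if "locus" in df.columns else "locus")
    return CredibleSet(locus_id=lid, members=members,
                       cumulative_pip=float(cum.iloc[k - 1]), target=target,
                       under_coverage=under)


def build_credible_sets(pip_table: pd.DataFrame, target: float = 0.95) -> list[CredibleSet]:
    """One credible set per ``locus`` in a PIP table."""
    return [build_credible_set(grp, target=target, locus_id=str(locus))
            for locus, grp in pip_table.groupby("locus", sort=True)]


def cs_to_genes(credible_sets, genes: pd.DataFrame) -> pd.DataFrame:
    """Map each credible set to the genes its members overlap.

    Intergenic-only sets are labelled as such, with the nearest gene on the
    same chromosome and its distance (bp from the variant to the closest
    interval edge) reported.
    """
    if isinstance(credible_sets, CredibleSet):
        credible_sets = [credible_sets]
    rows = []
    for cs in credible_sets:
        ann = gwas.map_variants_to_genes(cs.members, genes)
        hit_genes = sorted(set(ann.loc[ann["gene"].notna(), "gene"]))
        nearest, distance = None, np.nan
        if not hit_genes:
            nearest, distance = _nearest_gene(cs.members, genes)
        rows.append({
            "locus": cs.locus_id,
            "genes": ",".join(hit_genes),
            "n_genes": len(hit_genes),
            "intergenic": not hit_genes,
            "nearest_gene": nearest,
            "distance": distance,
        })
    return pd.DataFrame(rows)


def _nearest_gene(members: pd.DataFrame, genes: pd.DataFrame):
    best_gene, best_dist = None, np.inf
    for row in members.itertuples(index=False):
        chrom = str(row.chrom)
        sub = genes[genes["chrom"].astype(str) == chrom]
        for g in sub.itertuples(index=False):
            pos0 = int(row.pos) - 1
            if pos0 < g.start:
                d = g.start - pos0
            elif pos0 >= g.end:
                d = pos0 - (g.end - 1)
            else:
                d = 0
            if d < best_dist:
                best_gene, best_dist = g.gene, d
    return best_gene, (float(best_dist) if np.isfinite(best_dist) else np.nan)
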