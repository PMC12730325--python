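"""Packaged reference tables.

``candidate_genes.tsv`` is the published 45-gene candidate table for
heritable breast-cancer predisposition: per-gene evidence labels (a-i,
drawn from the overlap of FinnGen freeze 11/12 credible-set genes, Open
Targets genetic-association tiers, TWAS, PWAS and ExPheWAS), the
unvalidated-b-only exclusion flag, FinnGen coding-variant support counts,
subtype credible-set status, somatic-driver overlap, clinical-panel
membership and literature support.

``driver_overlap.tsv`` lists the genes shared between the
genetics-credible gene set and somatic driver-gene lists (tumor
suppressors / oncogenes from primary tumour samples and a pan-cancer
machine-learning driver screen).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_candidate_genes", "load_driver_overlap", "parse_labels"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("corewas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_candidate_genes() -> pd.DataFrame:
    """The 45-gene candidate evidence table (one row per gene)."""
    df = _read("candidate_genes.tsv")
    df["excluded"] = df["excluded"].astype(bool)
    return df


def load_driver_overlap() -> pd.DataFrame:
    """Genes overlapping somatic driver lists, with TSG/ONC category."""
    return _read("driver_overlap.tsv")


def parse_labels(value) -> frozenset[str]:
    """Parse a comma-joined evidence-label cell (``"c,d,g"``) to a set."""
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    value = str(value).strip()
    if not value:
        return frozenset()
    return frozenset(part.strip() for part in value.split(",") if part.strip())
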