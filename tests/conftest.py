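import itertools

import numpy as np
import pandas as pd
import pytest

from corewas import simulate


def brute_force_damage(genotypes, scores):
    """Exhaustive enumeration over all damage outcomes of every allele copy.

    Independent oracle for the Poisson-binomial (p0, p1): expands the gene
    into individual allele copies and sums path probabilities.
    """
    qs = []
    for g, s in zip(genotypes, scores):
        qs.extend([1.0 - s] * int(g))
    p0 = p1 = 0.0
    for bits in itertools.product((0, 1), repeat=len(qs)):
        pr = 1.0
        for b, q in zip(bits, qs):
            pr *= q if b else (1.0 - q)
        k = sum(bits)
        if k == 0:
            p0 += pr
        elif k == 1:
            p1 += pr
    return p0, p1


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 500-individual cohort with one dominant risk gene."""
    cfg = simulate.PopulationConfig(n_individuals=500, n_genes=20, seed=31)
    truth = simulate.SimTruth(
        (simulate.RiskGene("g0003", "dominant", simulate.DOMINANT_EFFECT),))
    return simulate.simulate_cohort(cfg, truth)


@pytest.fixture()
def gene_bed():
    return pd.DataFrame({
        "chrom": ["1", "1", "1"],
        "start": [99, 95, 1000],
        "end": [100, 200, 2000],
        "gene": ["tiny", "outer", "far"],
    })


@pytest.fixture()
def sumstat_frame():
    def make(n=10, seed=0, **overrides):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "chrom": ["1"] * n,
            "pos": np.arange(100, 100 + n),
            "ref": ["A"] * n,
            "alt": ["G"] * n,
            "af": rng.uniform(0.05, 0.5, n),
            "beta": rng.normal(0, 0.1, n),
            "se": rng.uniform(0.01, 0.05, n),
            "p": rng.uniform(1e-12, 1, n),
        })
        for col, val in overrides.items():
            df[col] = val
        return df
    return make
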