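"""Synthetic cohorts with planted dominant/recessive risk genes.

The generator emulates the statistical structure the downstream analysis
assumes: two case/control cohorts drawn from related populations (a
Balding-Nichols founder-drift law parameterised by Fst), Hardy-Weinberg
genotypes, variant functional-effect scores by class (synonymous /
missense / loss-of-function), and a liability-scale logistic phenotype in
which planted risk genes act through the *same* dominant/recessive damage
probabilities that :mod:`corewas.burden` computes -- so parameter recovery
is well-posed by construction.

Every stochastic operation takes an explicit seed or
:class:`numpy.random.Generator`; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from corewas import burden, datasets

__all__ = [
    "PopulationConfig",
    "RiskGene",
    "SimTruth",
    "Cohort",
    "drift_allele_freqs",
    "simulate_allele_freqs",
    "simulate_variant_table",
    "simulate_cohort",
    "export_summary_stats",
    "export_evidence_fixture",
    "simulate_single_causal_locus",
    "simulate_ot_scores",
]

# variant-class mixture and score laws (see docs/methods.md)
CLASS_PROBS = {"synonymous": 0.35, "missense": 0.50, "lof": 0.15}
#: founder-enriched allele-frequency window for damaging variants in
#: planted risk genes
RISK_AF_RANGE = (0.08, 0.25)
#: default liability effects (per unit damage probability)
DOMINANT_EFFECT = 1.25
RECESSIVE_EFFECT = 1.75
COVARIATE_EFFECTS = {"sex": 0.25, "pc1": 0.10, "pc2": 0.10}

GENE_LENGTH = 10_000
GENE_SPACING = 50_000
N_AUTOSOMES = 22


@dataclass
class PopulationConfig:
    """Shape of the simulated study.

    ``founder_fst`` is the Balding-Nichols divergence of population 2 from
    population 1 (0 = identical allele frequencies).  ``af_beta`` are the
    Beta-law parameters of the base allele-frequency distribution, clipped
    to [0.005, 0.5] so every simulated variant is polymorphic.
    """

    n_individuals: int = 2000
    n_genes: int = 100
    variants_per_gene: int = 8
    founder_fst: float = 0.0
    af_beta: tuple[float, float] = (0.4, 3.0)
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not (0.0 <= self.founder_fst < 1.0):
            raise ValueError("founder_fst must lie in [0, 1)")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.n_genes < 1 or self.variants_per_gene < 1:
            raise ValueError("n_genes and variants_per_gene must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class RiskGene:
    gene_id: str
    mode: str  # "dominant" | "recessive"
    effect: float

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown inheritance mode: {self.mode!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect size must be finite")


@dataclass
class SimTruth:
    """Planted ground truth: which genes carry risk, and how."""

    risk_genes: tuple[RiskGene, ...] = ()

    def __post_init__(self) -> None:
        self.risk_genes = tuple(self.risk_genes)

    @property
    def gene_ids(self) -> set[str]:
        return {rg.gene_id for rg in self.risk_genes}


@dataclass
class Cohort:
    """One simulated case/control cohort."""

    variants: pd.DataFrame       # variant_id, chrom, pos, ref, alt, gene, vclass, score, af
    genes: pd.DataFrame          # chrom, start, end, gene (BED-style, 0-based half-open)
    genotypes: np.ndarray        # (V, N) alt-allele counts in {0,1,2}
    phenotype: np.ndarray        # (N,) in {0,1}
    covariates: pd.DataFrame     # sex, pc1, pc2

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]


def gene_name(i: int) -> str:
    return f"g{i:04d}"


def drift_allele_freqs(af, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Founder-drifted allele frequencies via the Balding-Nichols law.

    Each drifted frequency is drawn from ``Beta(p (1-F)/F, (1-p)(1-F)/F)``
    around the source frequency ``p``, whose conditional variance is
    ``F p (1-p)``.  ``F = 0`` returns the input unchanged.
    """
    af = np.asarray(af, dtype=float)
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must lie in [0, 1)")
    if fst == 0.0:
        return af.copy()
    scale = (1.0 - fst) / fst
    return np.clip(rng.beta(af * scale, (1.0 - af) * scale), 1e-4, 1.0 - 1e-4)


def simulate_allele_freqs(cfg: PopulationConfig, n_variants: int | None = None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw base (population 1) AFs and founder-drifted (population 2) AFs."""
    rng = cfg.rng() if rng is None else rng
    m = n_variants if n_variants is not None else cfg.n_genes * cfg.variants_per_gene
    a, b = cfg.af_beta
    p1 = np.clip(rng.beta(a, b, size=m), 0.005, 0.5)
    p2 = drift_allele_freqs(p1, cfg.founder_fst, rng)
    return pd.DataFrame({"af_pop1": p1, "af_pop2": p2})


def simulate_variant_table(cfg: PopulationConfig, truth: SimTruth | None = None,
                           rng: np.random.Generator | None = None,
                           af: np.ndarray | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the variant annotation table and gene intervals.

    Genes are laid out round-robin on the 22 autosomes with fixed length
    and spacing; variants sit at random positions inside their gene.
    Damaging (non-synonymous) variants in planted risk genes get
    founder-enriched AFs so dominant and recessive carriers both exist at
    realistic cohort sizes.
    """
    rng = cfg.rng() if rng is None else rng
    truth = truth or SimTruth()
    m = cfg.n_genes * cfg.variants_per_gene
    unknown = truth.gene_ids - {gene_name(i) for i in range(cfg.n_genes)}
    if unknown:
        raise ValueError(f"risk genes absent from the annotation: {sorted(unknown)}")

    gene_idx = np.repeat(np.arange(cfg.n_genes), cfg.variants_per_gene)
    chrom = (gene_idx % N_AUTOSOMES) + 1
    gene_rank_on_chrom = gene_idx // N_AUTOSOMES
    start = gene_rank_on_chrom * GENE_SPACING + 10_000
    # one variant per position bin, so variant keys are unique within a gene
    bin_size = max(GENE_LENGTH // cfg.variants_per_gene, 1)
    slot = np.tile(np.arange(cfg.variants_per_gene), cfg.n_genes)
    pos = start + slot * bin_size + rng.integers(0, bin_size, size=m) + 1  # 1-based

    classes = rng.choice(list(CLASS_PROBS), size=m, p=list(CLASS_PROBS.values()))
    score = np.ones(m)
    mis = classes == "missense"
    lof = classes == "lof"
    score[mis] = rng.beta(2.0, 2.0, size=mis.sum())
    score[lof] = rng.uniform(0.0, 0.05, size=lof.sum())

    if af is None:
        a, b = cfg.af_beta
        af = np.clip(rng.beta(a, b, size=m), 0.005, 0.5)
    else:
        af = np.asarray(af, dtype=float)
        if af.shape != (m,):
            raise ValueError("af vector length must equal n_genes * variants_per_gene")

    genes = np.array([gene_name(i) for i in gene_idx])
    risky_damaging = np.isin(genes, sorted(truth.gene_ids)) & (classes != "synonymous")
    af = af.copy()
    af[risky_damaging] = rng.uniform(*RISK_AF_RANGE, size=risky_damaging.sum())

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=m)) % 4]

    variants = pd.DataFrame({
        "variant_id": [f"{c}:{p}:{r}:{a_}" for c, p, r, a_ in zip(chrom, pos, ref, alt)],
        "chrom": chrom.astype(str), "pos": pos, "ref": ref, "alt": alt,
        "gene": genes, "vclass": classes, "score": score, "af": af,
    })
    gene_rows = []
    for i in range(cfg.n_genes):
        c = str(i % N_AUTOSOMES + 1)
        s = (i // N_AUTOSOMES) * GENE_SPACING + 10_000
        gene_rows.append({"chrom": c, "start": s, "end": s + GENE_LENGTH,
                          "gene": gene_name(i)})
    return variants, pd.DataFrame(gene_rows)


def simulate_cohort(cfg: PopulationConfig, truth: SimTruth | None = None,
                    rng: np.random.Generator | None = None,
                    variants: pd.DataFrame | None = None,
                    genes: pd.DataFrame | None = None,
                    af: np.ndarray | None = None) -> Cohort:
    """Simulate genotypes (HWE given AF), covariates and a logistic phenotype.

    The linear predictor is ``logit(case_fraction)`` plus centred covariate
    effects plus, per planted risk gene, ``effect x damage probability``
    (dominant or recessive, as defined by the burden module), also centred
    so the realised case rate tracks ``case_fraction``.
    """
    rng = cfg.rng() if rng is None else rng
    truth = truth or SimTruth()
    if variants is None:
        variants, genes = simulate_variant_table(cfg, truth, rng=rng, af=af)
    elif genes is None:
        raise ValueError("variants supplied without gene intervals")

    usable = (variants["af"] > 0) & (variants["af"] < 1)
    if not usable.all():
        variants = variants[usable].reset_index(drop=True)
    n = cfg.n_individuals
    afv = variants["af"].to_numpy()
    G = rng.binomial(2, afv[:, None], size=(len(variants), n)).astype(np.int8)

    covars = pd.DataFrame({
        "sex": rng.integers(0, 2, size=n).astype(float),
        "pc1": rng.normal(size=n),
        "pc2": rng.normal(size=n),
    })
    lp = np.full(n, logit(cfg.case_fraction))
    for name, beta in COVARIATE_EFFECTS.items():
        x = covars[name].to_numpy()
        lp += beta * (x - x.mean())

    if truth.risk_genes:
        scores = burden.gene_scores(
            variants[variants["gene"].isin(truth.gene_ids)].reset_index(drop=True),
            G[variants["gene"].isin(truth.gene_ids).to_numpy()],
        )
        for rg in truth.risk_genes:
            ss = scores[rg.gene_id]
            dmg = ss.dom_damage if rg.mode == "dominant" else ss.rec_damage
            lp += rg.effect * (dmg - dmg.mean())

    y = rng.binomial(1, expit(lp)).astype(np.int8)
    return Cohort(variants=variants, genes=genes, genotypes=G,
                  phenotype=y, covariates=covars)


def _score_test(G: np.ndarray, y: np.ndarray, C: np.ndarray,
                chunk: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised covariate-adjusted efficient score test per variant.

    Returns the score ``U = g'(y - p)`` and its null variance
    ``V = g'Wg - g'WC (C'WC)^-1 C'Wg`` where ``p``/``W`` come from the
    covariates-only logistic fit.  The one-step estimator ``U/V`` and
    ``1/sqrt(V)`` serve as beta and SE, the standard large-panel GWAS
    approximation.
    """
    import statsmodels.api as sm

    fit = sm.Logit(y, C).fit(disp=0, maxiter=100)
    phat = fit.predict(C)
    W = phat * (1.0 - phat)
    resid = y - phat
    CW = C * W[:, None]
    Minv = np.linalg.inv(C.T @ CW)
    U = np.empty(G.shape[0])
    V = np.empty(G.shape[0])
    for lo in range(0, G.shape[0], chunk):
        g = G[lo:lo + chunk].astype(float)
        U[lo:lo + chunk] = g @ resid
        B = g @ CW
        V[lo:lo + chunk] = (g * g) @ W - np.einsum("vk,kl,vl->v", B, Minv, B)
    return U, V


def export_summary_stats(cohort: Cohort, method: str = "score",
                         covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-variant association summary statistics for one cohort.

    ``method="score"`` (default) is the vectorised score test;
    ``method="wald"`` fits a full per-variant logistic regression (slow,
    for small panels).  Monomorphic variants are emitted with null beta
    and ``flag="monomorphic"``.  AF is the empirical alt-allele count over
    ``2n``.
    """
    from scipy import stats as sps
    import statsmodels.api as sm

    y = cohort.phenotype.astype(float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    covars = cohort.covariates if covariates is None else covariates
    C = sm.add_constant(np.asarray(covars, dtype=float), has_constant="add")
    G = cohort.genotypes
    af = G.mean(axis=1) / 2.0
    mono = (G == G[:, :1]).all(axis=1)

    beta = np.full(G.shape[0], np.nan)
    se = np.full(G.shape[0], np.nan)
    p = np.full(G.shape[0], np.nan)
    keep = ~mono
    if method == "score":
        U, V = _score_test(G[keep], y, C)
        ok = V > 1e-12
        z = np.where(ok, U / np.sqrt(np.where(ok, V, 1.0)), np.nan)
        beta[keep] = np.where(ok, U / np.where(ok, V, 1.0), np.nan)
        se[keep] = np.where(ok, 1.0 / np.sqrt(np.where(ok, V, 1.0)), np.nan)
        p[keep] = 2.0 * sps.norm.sf(np.abs(z))
    elif method == "wald":
        import warnings

        idx = np.flatnonzero(keep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in idx:
                X = np.column_stack([C, G[i].astype(float)])
                try:
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                    beta[i] = fit.params[-1]
                    se[i] = fit.bse[-1]
                    p[i] = fit.pvalues[-1]
                except Exception:  # separation etc: leave flagged NaN
                    mono[i] = True
    else:
        raise ValueError(f"unknown method: {method!r}")

    out = cohort.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    out["af"] = af
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["flag"] = np.where(mono, "monomorphic", "ok")
    return out


def export_evidence_fixture() -> pd.DataFrame:
    """The packaged 45-candidate-gene evidence table (see corewas.datasets)."""
    return datasets.load_candidate_genes()


def simulate_single_causal_locus(n_variants: int = 50, signal: float = 4.0,
                                 rng: np.random.Generator | None = None,
                                 seed: int | None = None) -> tuple[pd.DataFrame, int]:
    """One fine-mapping locus with a single causal variant and exact PIPs.

    The causal variant's z-score is shifted by ``signal``; the posterior
    inclusion probability of candidate ``j`` under a uniform single-causal
    prior is the normalised likelihood ratio ``softmax(signal * z_j)``, the
    exact Bayesian posterior for this generative model -- so the PIPs are
    calibrated by construction and 95% credible sets should cover the true
    causal at >= 95% on average.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    causal = int(rng.integers(n_variants))
    z = rng.normal(size=n_variants)
    z[causal] += signal
    loglr = signal * z - 0.5 * signal**2
    w = np.exp(loglr - loglr.max())
    pip = w / w.sum()
    df = pd.DataFrame({
        "locus": "locus1",
        "chrom": "1",
        "pos": np.arange(1, n_variants + 1) * 100,
        "ref": "A", "alt": "G",
        "pip": pip,
    })
    df["variant_id"] = [f"1:{p}:A:G" for p in df["pos"]]
    return df, causal


def simulate_ot_scores(n_genes: int = 638, n_high: int = 208, theta: float = 0.5,
                       seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for an Open-Targets-style gene score table.

    Produces ``n_genes`` genes with genetic-association (GA) and global
    scores in [0, 1], exactly ``n_high`` of them with GA >= ``theta``.
    The per-gene scores are synthetic: only the table *shape* mirrors the
    real platform export.
    """
    rng = np.random.default_rng(seed)
    ga = np.concatenate([
        rng.uniform(theta, 1.0, size=n_high),
        rng.uniform(0.05, theta - 1e-6, size=n_genes - n_high),
    ])
    rng.shuffle(ga)
    global_score = np.clip(ga + rng.normal(0, 0.15, size=n_genes), 0.0, 1.0)
    return pd.DataFrame({
        "gene": [f"GENE{i:04d}" for i in range(n_genes)],
        "ga_score": ga,
        "global_score": global_score,
    })
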