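"""Gene-level burden scores and association tests.

Each coding variant carries a functional-effect score ``s`` in [0, 1]
(0 = complete loss of function, 1 = synonymous / no effect).  Treating each
alternative-allele copy as an independent damaging event with probability
``q = 1 - s``, the per-individual, per-gene Poisson-binomial probabilities

* ``p0`` -- no damaging event in the gene,
* ``p1`` -- exactly one damaging event,

yield the *dominant* damage probability ``1 - p0`` (at least one damaged
allele) and the *recessive* damage probability ``1 - p0 - p1`` (at least two
damaging events anywhere in the gene, which includes compound
heterozygotes).  The corresponding *effect scores* are the complements
``p0`` and ``p0 + p1``: higher values mean less functional damage, so a
risk gene shows a **negative** regression coefficient / z-score.

Association uses a combined logistic model: a 2-df likelihood-ratio test of
(covariates) vs (covariates + dominant effect score + recessive effect
score), with 1-df Wald tests per component and Cohen's d effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GeneScoreSet",
    "AssociationResult",
    "gene_damage_distribution",
    "gene_scores",
    "associate_gene",
    "associate_genes",
    "cohens_d",
    "adjust_multiple",
]

#: floor applied inside log-space products to avoid underflow; scores of
#: exactly zero are short-circuited before the floor matters.
SCORE_FLOOR = 1e-300


def gene_damage_distribution(genotypes, scores):
    """Probabilities of zero / exactly one damaging event in one gene.

    Parameters
    ----------
    genotypes : array-like
        Alternative-allele counts, shape ``(V,)`` for one individual or
        ``(V, N)`` for ``N`` individuals; entries in {0, 1, 2}.
    scores : array-like
        Functional-effect score per variant, shape ``(V,)``, each in [0, 1].

    Returns
    -------
    (p0, p1) : floats or ``(N,)`` arrays
        ``p0 = prod_v s_v**g_v`` and the exactly-one-event Poisson-binomial
        term.  Accumulation is in log space, so genes with thousands of
        variants are numerically safe.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(genotypes)
    if s.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if np.any((s < 0) | (s > 1)) or np.any(np.isnan(s)):
        raise ValueError("scores must lie in [0, 1]")
    if g.shape[0] != s.shape[0]:
        raise ValueError("genotypes and scores disagree on variant count")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotype counts must be in {0, 1, 2}")

    scalar = g.ndim == 1
    G = g[:, None] if scalar else g
    G = G.astype(float)

    zero = s == 0.0
    nz = ~zero
    # certain damaging events contributed by score-0 variants
    n_certain = G[zero].sum(axis=0) if zero.any() else np.zeros(G.shape[1])

    log_s = np.log(np.maximum(s[nz], SCORE_FLOOR))
    log_p0 = log_s @ G[nz]
    p0_nz = np.exp(log_p0)
    # sum of g * q/s terms: d/ds expansion of the exactly-one probability
    ratio = (1.0 - s[nz]) / np.maximum(s[nz], SCORE_FLOOR)
    R = ratio @ G[nz]

    p0 = np.where(n_certain == 0, p0_nz, 0.0)
    p1 = np.where(
        n_certain == 0, p0_nz * R, np.where(n_certain == 1, p0_nz, 0.0)
    )
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0 - p0)
    if scalar:
        return float(p0[0]), float(p1[0])
    return p0, p1


@dataclass
class GeneScoreSet:
    """Per-individual damage distribution for one gene.

    ``dom_score``/``rec_score`` are the effect scores used as regressors
    (higher = less damage); ``dom_damage``/``rec_damage`` their complements.
    """

    gene_id: str
    p0: np.ndarray
    p1: np.ndarray

    @property
    def dom_score(self) -> np.ndarray:
        return self.p0

    @property
    def rec_score(self) -> np.ndarray:
        return self.p0 + self.p1

    @property
    def dom_damage(self) -> np.ndarray:
        return 1.0 - self.p0

    @property
    def rec_damage(self) -> np.ndarray:
        return 1.0 - self.p0 - self.p1


def gene_scores(variants: pd.DataFrame, genotypes: np.ndarray,
                gene_col: str = "gene", score_col: str = "score") -> dict[str, GeneScoreSet]:
    """Aggregate a variant table + genotype matrix into per-gene score sets.

    ``variants`` rows correspond to rows of ``genotypes`` (shape ``(V, N)``).
    """
    if len(variants) != genotypes.shape[0]:
        raise ValueError("variant table and genotype matrix disagree on variant count")
    out: dict[str, GeneScoreSet] = {}
    for gene, idx in variants.groupby(gene_col, sort=True).indices.items():
        p0, p1 = gene_damage_distribution(genotypes[idx], variants[score_col].to_numpy()[idx])
        out[str(gene)] = GeneScoreSet(str(gene), p0, p1)
    return out


@dataclass
class AssociationResult:
    gene_id: str
    z_dom: float
    z_rec: float
    z_combined: float
    p_dom: float
    p_rec: float
    p_combined: float
    d_dom: float
    d_rec: float
    inferred_mode: str
    ok: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "z_dom": self.z_dom, "z_rec": self.z_rec, "z_combined": self.z_combined,
            "p_dom": self.p_dom, "p_rec": self.p_rec, "p_combined": self.p_combined,
            "d_dom": self.d_dom, "d_rec": self.d_rec,
            "mode": self.inferred_mode, "ok": self.ok, "note": self.note,
        }


def cohens_d(case_scores, control_scores) -> float:
    """Standardised mean difference (case mean - control mean) / pooled SD.

    Pooled SD uses the usual n-1 denominator per group.  Returns NaN when
    the pooled SD is zero (undefined effect) or a group has < 2 members.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def _design(covariates) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return sm.add_constant(C, has_constant="add")


def _fit_logit(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=100)


_NULL_RESULT_KW = dict(
    z_dom=np.nan, z_rec=np.nan, z_combined=np.nan,
    p_dom=np.nan, p_rec=np.nan, p_combined=np.nan,
)


def associate_gene(scores: GeneScoreSet, phenotype, covariates,
                   mode_alpha: float = 0.025, _null_fit=None) -> AssociationResult:
    """Test one gene's dominant/recessive effect scores against case status.

    The combined p-value comes from a likelihood-ratio test of the logistic
    model with both effect scores against the covariates-only null (2 df
    when both components are informative).  ``inferred_mode`` is the
    component significant at ``mode_alpha`` (default 0.05 Bonferroni-split
    across the two components); ``hybrid`` when both are, and the smaller
    Wald p-value when neither reaches it.

    Degenerate genes (constant scores, perfect separation, non-convergence)
    return a flagged result with NaN p-values rather than raising.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.min() == y.max():
        raise ValueError("phenotype needs at least one case and one control")
    dom = np.asarray(scores.dom_score, dtype=float)
    rec = np.asarray(scores.rec_score, dtype=float)
    d_dom = cohens_d(dom[y == 1], dom[y == 0])
    d_rec = cohens_d(rec[y == 1], rec[y == 0])

    components: list[tuple[str, np.ndarray]] = []
    note = ""
    if dom.std() > 0:
        components.append(("dominant", dom))
    else:
        note = "constant dominant score"
    if rec.std() > 0:
        # drop the recessive column when numerically identical to the
        # dominant one (no individual can reach two events)
        if dom.std() > 0 and np.allclose(rec, dom, rtol=0.0, atol=1e-15):
            note = "recessive score identical to dominant"
        else:
            components.append(("recessive", rec))
    elif not note:
        note = "constant recessive score"

    if not components:
        return AssociationResult(scores.gene_id, d_dom=d_dom, d_rec=d_rec,
                                 inferred_mode="hybrid", ok=False,
                                 note="zero-variance gene scores", **_NULL_RESULT_KW)

    Xnull = _design(covariates)
    Xfull = np.column_stack([Xnull] + [c for _, c in components])
    try:
        null_fit = _null_fit if _null_fit is not None else _fit_logit(y, Xnull)
        full_fit = _fit_logit(y, Xfull)
        if not full_fit.mle_retvals.get("converged", True):
            raise RuntimeError("logit did not converge")
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeError) as exc:
        return AssociationResult(scores.gene_id, d_dom=d_dom, d_rec=d_rec,
                                 inferred_mode="hybrid", ok=False,
                                 note=f"fit failed: {exc}", **_NULL_RESULT_KW)

    k = len(components)
    llr = 2.0 * (full_fit.llf - null_fit.llf)
    p_combined = float(stats.chi2.sf(max(llr, 0.0), df=k))
    z_combined = float(stats.norm.isf(p_combined / 2.0)) if p_combined > 0 else np.inf
    # sign convention: negative z on effect scores = risk gene
    z_combined *= np.sign(sum(full_fit.params[Xnull.shape[1]:]))

    wald = {"dominant": (np.nan, np.nan), "recessive": (np.nan, np.nan)}
    for j, (name, _) in enumerate(components):
        b = full_fit.params[Xnull.shape[1] + j]
        se = full_fit.bse[Xnull.shape[1] + j]
        z = b / se if se > 0 else np.nan
        wald[name] = (float(z), float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan)

    sig = [name for name, _ in components if wald[name][1] < mode_alpha]
    if len(sig) == 2:
        mode = "hybrid"
    elif len(sig) == 1:
        mode = sig[0]
    else:
        mode = min((name for name, _ in components),
                   key=lambda n: wald[n][1] if np.isfinite(wald[n][1]) else np.inf)

    return AssociationResult(
        scores.gene_id,
        z_dom=wald["dominant"][0], z_rec=wald["recessive"][0],
        z_combined=float(z_combined),
        p_dom=wald["dominant"][1], p_rec=wald["recessive"][1],
        p_combined=p_combined, d_dom=d_dom, d_rec=d_rec,
        inferred_mode=mode, ok=True, note=note,
    )


def associate_genes(score_sets, phenotype, covariates,
                    mode_alpha: float = 0.025) -> pd.DataFrame:
    """Run :func:`associate_gene` for many genes, reusing the null fit."""
    y = np.asarray(phenotype, dtype=float)
    null_fit = _fit_logit(y, _design(covariates))
    rows = []
    iterator = score_sets.values() if isinstance(score_sets, dict) else score_sets
    for scores in iterator:
        rows.append(associate_gene(scores, y, covariates,
                                   mode_alpha=mode_alpha, _null_fit=null_fit).to_dict())
    return pd.DataFrame(rows)


def adjust_multiple(pvalues, method: str = "bh", alpha: float = 0.05,
                    threshold: float | None = None):
    """Multiple-testing adjustment.

    ``method`` is ``"bh"`` (Benjamini-Hochberg), ``"bonferroni"``, or
    ``"fixed"`` (a fixed genome-wide / exome-scale threshold such as 5e-8 or
    5e-7, in which case ``threshold`` is required and q-values are returned
    unchanged).  Returns ``(qvalues, reject)`` arrays.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold mode requires a threshold")
        return p.copy(), p <= threshold
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    reject, q, _, _ = multipletests(p, alpha=alpha, method=key)
    return q, reject
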