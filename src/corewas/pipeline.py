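"""End-to-end orchestration: synthetic cohorts through evidence assembly.

``run_pipeline`` executes the enabled stages in dependency order --
simulate two related cohorts, gene-level burden association, GWAS
coherence filtering with inflation QC, credible sets on simulated loci,
cross-cohort concordance, and evidence integration on the packaged
candidate table -- writing one TSV per stage plus a run manifest (package
version, config hash, seeds, per-stage record accounting) that suffices to
reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import corewas
from corewas import burden, cohorts, credible, datasets, evidence, gwas, simulate

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

ALL_STAGES = ("simulate", "pwas", "gwasfilter", "credsets", "concord", "evidence")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "corewas_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # cohort shape
    n_individuals: int = 2000
    n_genes: int = 100
    variants_per_gene: int = 8
    founder_fst: float = 0.05
    case_fraction: float = 0.5
    # planted truth
    dominant_genes: tuple[str, ...] = ("g0003",)
    recessive_genes: tuple[str, ...] = ("g0007",)
    dominant_effect: float = simulate.DOMINANT_EFFECT
    recessive_effect: float = simulate.RECESSIVE_EFFECT
    # thresholds
    maf_threshold: float = 0.01
    coherence: float = 0.75
    sig_threshold: float = gwas.GENOME_WIDE_P
    cs_target: float = 0.95
    n_loci: int = 20
    moderate_beta: float = 0.1
    ga_threshold: float = 0.5
    ga_high_threshold: float = 0.75

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        if not (0.5 <= self.coherence <= 1.0):
            raise ValueError("coherence must lie in [0.5, 1]")
        if not (0 < self.cs_target <= 1.0):
            raise ValueError("cs_target must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["dominant_genes"] = list(d["dominant_genes"])
        d["recessive_genes"] = list(d["recessive_genes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("stages", "dominant_genes", "recessive_genes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _truth(cfg: PipelineConfig) -> simulate.SimTruth:
    return simulate.SimTruth(
        tuple(simulate.RiskGene(g, "dominant", cfg.dominant_effect)
              for g in cfg.dominant_genes)
        + tuple(simulate.RiskGene(g, "recessive", cfg.recessive_effect)
                for g in cfg.recessive_genes))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dict (also written)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "corewas",
        "version": corewas.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    cfg.to_yaml(outdir / "config.yaml")

    ctx: dict = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            counts = _STAGE_FUNCS[stage](cfg, ctx, outdir)
        except Exception as exc:  # preserve partial outputs, halt with scope
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {"status": "ok", **counts}
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_simulate(cfg: PipelineConfig, ctx: dict, outdir: Path) -> dict:
    pop = simulate.PopulationConfig(
        n_individuals=cfg.n_individuals, n_genes=cfg.n_genes,
        variants_per_gene=cfg.variants_per_gene, founder_fst=cfg.founder_fst,
        case_fraction=cfg.case_fraction, seed=cfg.seed)
    truth = _truth(cfg)
    rng = pop.rng()
    # one shared variant panel; cohort B's AFs drift from cohort A's
    variants, genes = simulate.simulate_variant_table(pop, truth, rng=rng)
    af_b = simulate.drift_allele_freqs(variants["af"], cfg.founder_fst, rng)
    a = simulate.simulate_cohort(pop, truth, rng=rng, variants=variants, genes=genes)
    b = simulate.simulate_cohort(pop, truth, rng=rng,
                                 variants=variants.assign(af=af_b), genes=genes)
    ctx.update(pop=pop, truth=truth, cohort_a=a, cohort_b=b)
    a.variants.to_csv(outdir / "variants_cohort_a.tsv", sep="\t", index=False)
    a.genes.to_csv(outdir / "gene_intervals.tsv", sep="\t", index=False)
    pheno = a.covariates.copy()
    pheno.insert(0, "phenotype", a.phenotype)
    pheno.to_csv(outdir / "phenotype_covariates_a.tsv", sep="\t", index=False)
    return {"n_variants": len(a.variants), "n_individuals": a.n_individuals,
            "n_cases": int(a.phenotype.sum())}


def _stage_pwas(cfg: PipelineConfig, ctx: dict, outdir: Path) -> dict:
    a = ctx["cohort_a"]
    scores = burden.gene_scores(a.variants, a.genotypes)
    res = burden.associate_genes(scores, a.phenotype, a.covariates)
    res["q_bh"], res["reject_bh"] = burden.adjust_multiple(
        res["p_combined"].fillna(1.0), method="bh")
    res.to_csv(outdir / "pwas_associations.tsv", sep="\t", index=False)
    ctx["pwas"] = res
    return {"n_genes": len(res), "n_flagged": int((~res["ok"]).sum()),
            "n_significant_bh": int(res["reject_bh"].sum())}


def _stage_gwasfilter(cfg: PipelineConfig, ctx: dict, outdir: Path) -> dict:
    a = ctx["cohort_a"]
    ss = simulate.export_summary_stats(a)
    ss.to_csv(outdir / "summary_stats_a.tsv", sep="\t", index=False)
    ok = ss[ss["flag"] == "ok"]
    kept = gwas.filter_maf(ok, cfg.maf_threshold)
    ann = gwas.map_variants_to_genes(kept, a.genes)
    # exome-scale threshold on this synthetic panel size
    sig = ann[ann["p"] < gwas.EXOME_SCALE_P]
    support = gwas.gene_coherence_filter(sig, coherence=cfg.coherence)
    support.to_csv(outdir / "gene_support.tsv", sep="\t", index=False)
    infl = gwas.genomic_inflation(ok["p"].dropna())
    infl.qq.to_csv(outdir / "qq_data.tsv", sep="\t", index=False)
    ctx["summary_a"] = ss
    return {"n_input": len(ss), "n_monomorphic": int((ss["flag"] != "ok").sum()),
            "n_after_maf": len(kept), "n_significant": int(sig["variant_id"].nunique()),
            "n_genes_pass": int(support["passes"].sum()) if len(support) else 0,
            "lambda_gc": round(infl.lambda_gc, 4)}


def _stage_credsets(cfg: PipelineConfig, ctx: dict, outdir: Path) -> dict:
    rng = np.random.default_rng(cfg.seed + 1)
    frames = []
    for i in range(cfg.n_loci):
        locus, _ = simulate.simulate_single_causal_locus(rng=rng)
        locus["locus"] = f"locus{i:03d}"
        frames.append(locus)
    pip_table = pd.concat(frames, ignore_index=True)
    sets = credible.build_credible_sets(pip_table, target=cfg.cs_target)
    rows = [m.assign(locus=cs.locus_id) for cs in sets for m in (cs.members,)]
    pd.concat(rows, ignore_index=True).to_csv(outdir / "credible_sets.tsv",
                                              sep="\t", index=False)
    return {"n_loci": len(sets),
            "mean_cs_size": round(float(np.mean([len(cs) for cs in sets])), 2),
            "n_under_coverage": sum(cs.under_coverage for cs in sets)}


def _stage_concord(cfg: PipelineConfig, ctx: dict, outdir: Path) -> dict:
    ss_a = ctx.get("summary_a")
    if ss_a is None:
        ss_a = simulate.export_summary_stats(ctx["cohort_a"])
    ss_b = simulate.export_summary_stats(ctx["cohort_b"])
    ok_a = ss_a[ss_a["flag"] == "ok"]
    ok_b = ss_b[ss_b["flag"] == "ok"]
    report = cohorts.match_variants(ok_a, ok_b)
    conc = cohorts.concordance_report(report.matches, moderate_beta=cfg.moderate_beta)
    report.matches.to_csv(outdir / "variant_matches.tsv", sep="\t", index=False)
    conc.discordant.to_csv(outdir / "discordant_variants.tsv", sep="\t", index=False)
    return {"n_matches": conc.n_matches,
            "missing_from_b": round(report.missing_from_b, 4),
            "sign_concordance": round(conc.sign_concordance, 4),
            "sign_concordance_significant": (
                round(conc.sign_concordance_significant, 4)
                if np.isfinite(conc.sign_concordance_significant) else None),
            "n_significant_pairs": conc.n_significant_pairs,
            "moderate_fraction": round(conc.moderate_fraction, 4)}


def _stage_evidence(cfg: PipelineConfig, ctx: dict, outdir: Path) -> dict:
    table = datasets.load_candidate_genes()
    core = evidence.assemble_core(table)
    core.table.to_csv(outdir / "core_gene_list.tsv", sep="\t", index=False)
    drivers = datasets.load_driver_overlap()
    tsg_overlap = evidence.hypergeometric_overlap(
        N=evidence.PROTEIN_CODING_UNIVERSE, K=52, n=208,
        k=int((drivers["category"] == "TSG").loc[
            drivers["driver_list"] == "primary_bc"].sum()))
    pd.DataFrame([dataclasses.asdict(tsg_overlap)]).to_csv(
        outdir / "overlap_tests.tsv", sep="\t", index=False)
    return {"n_candidates": core.n_candidates, "n_core": core.n_core,
            "n_excluded": core.n_excluded,
            "n_multi_evidence": core.n_multi_evidence,
            "tsg_overlap_p": float(tsg_overlap.p_upper)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "pwas": _stage_pwas,
    "gwasfilter": _stage_gwasfilter,
    "credsets": _stage_credsets,
    "concord": _stage_concord,
    "evidence": _stage_evidence,
}
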