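# Methods

## Gene burden model

Each variant *v* in gene *g* carries a functional-effect score
*s*ᵥ ∈ [0, 1] interpreted as the probability that the protein retains its
function in the presence of one alternative allele (0 = loss of function,
1 = synonymous). Scores are inputs; the package does not train the
variant-effect predictor. For an individual with genotype *g*ᵥ ∈ {0, 1, 2}
alternative-allele copies, each copy is treated as an independent damaging
event with probability *q*ᵥ = 1 − *s*ᵥ. No phase information is used:
biobank genotypes are unphased, and the ≥ 2-event recessive definition
deliberately counts compound heterozygotes as well as homozygotes.

The Poisson-binomial terms are

* *p₀* = ∏ᵥ *s*ᵥ^{gᵥ} — probability of zero damaging events,
* *p₁* = *p₀* · Σᵥ gᵥ qᵥ / sᵥ — probability of exactly one,

accumulated in log space with a floor of 1e−300; variants with *s* = 0
(certain events) are short-circuited exactly: one certain copy forces
*p₀* = 0 and *p₁* = P(no event elsewhere); two force *p₀* = *p₁* = 0.
The *effect scores* used as regressors are *p₀* (dominant) and *p₀* + *p₁*
(recessive); higher = less damage, so risk genes have negative
coefficients and negative Cohen's *d* (case mean minus control mean over
the pooled n−1 SD).

**Association.** The combined test is a likelihood-ratio test of
logistic(phenotype ~ covariates + dominant score + recessive score)
against the covariates-only null — 2 df when both components are
informative, 1 df when one is constant or numerically identical to the
other (genes where no individual can reach two events). Per-component
Wald z/p accompany it. The inferred inheritance mode is the component
significant at `mode_alpha` (default 0.025, a Bonferroni split of 0.05
across the two components); *hybrid* when both are, and the smaller Wald
p when neither reaches the threshold. Degenerate genes (zero variance,
separation, non-convergence) yield flagged results with NaN p-values
rather than exceptions, so proteome-scale scans never abort.

The 2-df LRT was chosen because it nests both single-mode tests: a
significant combined result means at least one burden mode is associated.
Simulation at n = 2000 (thousands of null genes across independent
streams) puts its empirical size at ≈ 0.05, which the acceptance suite
re-verifies on every run.

## Per-variant summary statistics

`export_summary_stats` defaults to the covariate-adjusted efficient score
test, vectorised over variants: with the covariates-only logistic fit
giving fitted probabilities p̂ and weights W = p̂(1 − p̂), the per-variant
score is U = gᵀ(y − p̂) with null variance
V = gᵀWg − gᵀWC (CᵀWC)⁻¹ CᵀWg, giving z = U/√V, one-step β = U/V and
SE = 1/√V. This is the standard large-panel approximation (what
biobank-scale GWAS tools use) and makes null-calibration checks at 2×10⁴
variants routine; `method="wald"` fits a full per-variant logistic
regression for small panels. Monomorphic variants are emitted with null β
and a flag; AF is the empirical allele count over 2n.

## Synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes —
it makes no claim to reproduce any real biobank:

* **Allele frequencies**: base AF ~ Beta(0.4, 3) clipped to [0.005, 0.5]
  (a rare-skewed folded-SFS-like shape). A related population's AFs
  follow the Balding–Nichols law Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F = `founder_fst`; conditional variance F·p(1−p); F = 0 gives identical
  populations. Drift pushes rare variants to loss, so a drifted cohort
  shows the variant-missingness pattern seen when a founder population is
  compared with a broader one.
* **Genotypes**: Binomial(2, AF) per individual — exact HWE, no LD. Gene
  intervals are laid out round-robin on the 22 autosomes (10 kb genes,
  50 kb spacing), one variant per position bin so keys are unique.
* **Variant classes**: synonymous/missense/LoF at 0.35/0.50/0.15 with
  scores 1, Beta(2, 2), and U(0, 0.05) respectively.
* **Phenotype**: Bernoulli(logistic(η)) with
  η = logit(`case_fraction`) + centred covariate effects (sex 0.25, two
  PCs 0.10 each) + Σ effect × (damage − mean damage) over planted risk
  genes, where damage is the *same* dominant or recessive probability the
  burden module computes — so parameter recovery is well-posed by
  construction. Default `case_fraction` 0.5 (a balanced case/control
  design); default planted effects 1.25 (dominant) and 1.75 (recessive)
  per unit damage probability, chosen once for clear detectability at the
  cohort sizes used in the checks (n = 2000–5000). Damaging variants in
  risk genes get founder-enriched AFs U(0.08, 0.25) so both dominant
  carriers and compound heterozygotes exist at those sizes.
* **Covariates** default to sex + 2 synthetic PCs; real-biobank covariate
  batteries (dozens of PCs, batches, centres) are cohort-specific and out
  of scope. Every stochastic operation takes an explicit seed or
  Generator; there is no global RNG state.

What passing tests on this generator do **not** show: behaviour under LD
(variant-to-gene mapping errors from correlated variants), imputation
artefacts, X-chromosome dosage, case/control imbalance at biobank
prevalence, or confounding population structure beyond the simple PC
model.

**Fine-mapping loci.** `simulate_single_causal_locus` draws one causal
variant whose z-score is shifted by `signal` (default 4) among standard
normal noise; PIPs are the exact single-causal posterior
softmax(signal·z). Because the posterior matches the generative model,
95% credible sets cover the true causal ≈ 95% of the time — the
calibration the coverage check exercises.

## Credible sets

Variants are ranked by PIP (ties broken by position, then alleles, for
byte-reproducible output); the credible set is the minimal prefix whose
cumulative PIP reaches the target (default 0.95). Loci whose total PIP
falls short return all variants with an under-coverage flag. Duplicate
variant ids are rejected at construction.

## GWAS filters and QC

Gene intervals are BED 0-based half-open on disk; summary-stat positions
1-based; conversion happens only at the mapping boundary. Coding-gene
mode drops intergenic records and (by default) sex chromosomes. The
direction-coherence threshold — the fraction of a gene's significant
variants sharing the modal β sign — defaults to 0.75 ("the vast
majority"), configurable; genes with a single supporting variant never
pass. Directionality is assessed among the significant records handed to
the filter; callers choose the significance cut (5e-8 genome-wide and
5e-7 exome-scale constants are exported). λ_GC is the median observed
1-df χ² over 0.4549. VIFs are 1/(1 − R²) from regressing each covariate
(plus intercept) on the rest, flagged at 5 and 50.

## Cross-cohort matching

Exact chrom:pos:ref:alt join with one flip rule: a ref/alt-swapped match
negates β and complements AF (an involution). A/T and C/G pairs are never
flipped by default (strand ambiguity); a key whose direct *and* swapped
forms both exist in the other cohort is ambiguous and excluded.
Missingness is reported per cohort without distinguishing QC loss from
true absence — the data do not support that distinction. Overall sign
concordance over mostly-null panels sits near 0.5 by construction; the
informative statistic is concordance among pairs significant in both
cohorts (threshold configurable, default 1e-4). The "rare" AF window for
scatter output defaults to [0.001, 0.1]. No liftover, LD-proxy matching
or meta-analysis: cohorts are compared by replication only.

## Evidence integration

Label rules are predicates over source memberships
{FG11, FG12, OT0.5, OT0.75, TWAS, PWAS, ExPheWAS}. Only four labels are
pinned by the published table: d = FG11 ∧ FG12 ∧ OT0.75 ∧ TWAS,
b = OT0.75 ∧ TWAS without FinnGen support, g = PWAS, i = ExPheWAS; the
rest are user-configurable, and core-list assembly on the shipped
45-gene fixture uses the printed labels directly, so it does not depend
on rule guesses. The exclusion rule removes genes whose label set is
*exactly* a disqualifying singleton (default {b}); adding evidence can
therefore never demote a gene, and assembly is idempotent (duplicate rows
merge by label union). Overlap tests use the exact hypergeometric upper
tail summed as log-binomials (log-gamma + logsumexp); the binomial
support test requires its null proportion explicitly, since no universal
background rate for literature support exists. The default overlap
universe is 18,053 protein-coding genes, overridable.

## Problem sizes in the checks

The automated checks run at sizes chosen to give tight Monte-Carlo error
at interactive runtimes: 1000 null cohorts of n = 2000 (3 genes each) for
test size; 2×10⁴ null variants for λ_GC (sampling SD ≈ 0.016); 20 seeds
of n = 5000 × 200 genes for dominant/recessive recovery; 10⁴ random PIP
vectors plus 1000 loci for credible-set properties; replication
concordance at n = 10⁴ versus n = 500.

## Known limitations

* No LD, so variant-to-gene mis-mapping — a dominant error mode in real
  GWAS interpretation — is not emulated.
* The recessive score is undetectable when damaging alleles are too rare
  for compound heterozygotes; such genes degrade to a 1-df dominant test
  and are noted in the result's `note` field.
* The score-test β is a one-step approximation; for very strong effects
  or very rare variants the Wald path gives better effect estimates.
* Evidence labels a, c, e, f, h have no default predicates; workflows
  relying on them must supply a configuration.
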