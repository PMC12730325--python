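"""Evidence integration: OT filters, overlap statistics, labels, core list."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corewas import datasets, evidence, simulate


class TestOtThresholdFilter:
    def test_synthetic_ot_table_reproduces_published_counts(self):
        ot = simulate.simulate_ot_scores()
        assert len(ot) == 638
        assert len(evidence.ot_threshold_filter(ot, 0.5)) == 208

    def test_zero_threshold_is_identity(self):
        ot = simulate.simulate_ot_scores(n_genes=20, n_high=5)
        assert len(evidence.ot_threshold_filter(ot, 0.0)) == 20

    def test_above_one_threshold_is_empty(self):
        ot = simulate.simulate_ot_scores(n_genes=20, n_high=5)
        assert len(evidence.ot_threshold_filter(ot, 1.01)) == 0

    def test_out_of_range_scores_rejected(self):
        df = pd.DataFrame({"gene": ["A"], "ga_score": [1.5]})
        with pytest.raises(ValueError):
            evidence.ot_threshold_filter(df)


class TestScoreGapPrioritize:
    def external_fixture(self):
        # synthetic stand-in: known predisposition genes whose global
        # (all-evidence) score exceeds the genetic-association score
        strong = ["ATM", "BRCA2", "RAD51B", "PALB2", "ESR1",
                  "CCNE1", "PTPN11", "DNMT3A", "ERBB4", "C11orf65"]
        rows = [{"gene": g, "ga_score": 0.55, "global_score": 0.85} for g in strong]
        rows += [{"gene": f"N{i}", "ga_score": 0.6, "global_score": 0.5}
                 for i in range(30)]
        return pd.DataFrame(rows), strong

    def test_externally_supported_genes_top_the_ranking(self):
        df, strong = self.external_fixture()
        ranked = evidence.score_gap_prioritize(df, "external-support", top=10)
        assert set(ranked["gene"]) == set(strong)

    def test_equal_scores_keep_input_order(self):
        df = pd.DataFrame({"gene": list("abcd"), "ga_score": [0.5] * 4,
                           "global_score": [0.5] * 4})
        ranked = evidence.score_gap_prioritize(df, "external-support")
        assert list(ranked["gene"]) == list("abcd")

    def test_direction_reversal_flips_extremes(self):
        df = pd.DataFrame({"gene": ["hi", "lo"], "ga_score": [0.9, 0.2],
                           "global_score": [0.2, 0.9]})
        ext = evidence.score_gap_prioritize(df, "external-support")
        gen = evidence.score_gap_prioritize(df, "genetic-only")
        assert ext["gene"].iloc[0] == "lo" and gen["gene"].iloc[0] == "hi"


class TestHypergeometricOverlap:
    def test_zero_overlap_has_probability_one(self):
        assert evidence.hypergeometric_overlap(100, 10, 10, 0).p_upper == 1.0

    def test_tiny_universe_full_enumeration(self):
        # N=4, K=2, n=2, k=2: one favourable draw of six
        assert evidence.hypergeometric_overlap(4, 2, 2, 2).p_upper == \
            pytest.approx(1 / 6)

    def test_driver_overlap_is_significant(self):
        ot = evidence.hypergeometric_overlap(18053, 52, 208, 6)
        assert ot.p_upper < 0.01
        assert ot.p_upper == pytest.approx(
            stats.hypergeom.sf(5, 18053, 52, 208), rel=1e-10)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            evidence.hypergeometric_overlap(10, 5, 5, 6)

    def test_exhaustive_enumeration_small_universes(self):
        """Agreement with direct enumeration over all draws, N <= 8."""
        for N in (4, 6, 8):
            universe = list(range(N))
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    marked = set(universe[:K])
                    draws = list(itertools.combinations(universe, n))
                    for k in range(0, min(K, n) + 1):
                        exact = sum(len(marked & set(d)) >= k for d in draws) / len(draws)
                        got = evidence.hypergeometric_overlap(N, K, n, k).p_upper
                        assert got == pytest.approx(exact, abs=1e-12), (N, K, n, k)


class TestBinomialSupportTest:
    def test_all_successes_closed_form(self):
        assert evidence.binomial_support_test(5, 5, 0.5) == pytest.approx(0.5**5)

    def test_zero_successes_is_one(self):
        assert evidence.binomial_support_test(0, 7, 0.3) == 1.0

    @pytest.mark.parametrize("p0", [0.2, 0.3, 0.4, 0.5])
    def test_matches_term_by_term_summation(self, p0):
        k, n = 11, 15
        direct = sum(math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
                     for j in range(k, n + 1))
        assert evidence.binomial_support_test(k, n, p0) == pytest.approx(direct, rel=1e-12)

    def test_invalid_null_proportion_rejected(self):
        with pytest.raises(ValueError):
            evidence.binomial_support_test(1, 2, 0.0)


class TestAssignLabels:
    def test_ot75_twas_only_is_b(self):
        assert evidence.assign_labels({"OT0.75", "TWAS"}) == {"b"}

    def test_full_quadruple_is_d_not_b(self):
        labels = evidence.assign_labels({"FG11", "FG12", "OT0.75", "TWAS"})
        assert "d" in labels and "b" not in labels

    def test_pwas_is_g_and_exphewas_is_i(self):
        assert evidence.assign_labels({"PWAS"}) == {"g"}
        assert evidence.assign_labels({"PWAS", "ExPheWAS"}) == {"g", "i"}

    def test_empty_membership_yields_no_labels(self):
        assert evidence.assign_labels(set()) == frozenset()

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            evidence.assign_labels({"GWAS-Catalog"})


class TestAssembleCore:
    def test_candidate_table_counts(self):
        core = evidence.assemble_core(datasets.load_candidate_genes())
        assert core.n_candidates == 45
        assert core.n_multi_evidence == 13
        assert core.n_excluded == 7
        assert core.n_core == 38

    def test_exclusions_match_flagged_rows(self):
        table = datasets.load_candidate_genes()
        core = evidence.assemble_core(table)
        flagged = set(table.loc[table["excluded"], "gene"])
        assert set(core.table.loc[~core.table["core"], "gene"]) == flagged

    def test_b_with_additional_support_stays_core(self):
        core = evidence.assemble_core(datasets.load_candidate_genes())
        t = core.table.set_index("gene")
        for gene in ("MAP3K1", "MRPS30", "NEK10", "TOX3"):
            assert t.loc[gene, "core"]

    def test_idempotent(self):
        core1 = evidence.assemble_core(datasets.load_candidate_genes())
        core2 = evidence.assemble_core(core1.table, label_col="labels")
        pd.testing.assert_frame_equal(core1.table, core2.table)

    def test_adding_evidence_never_demotes(self):
        base = pd.DataFrame({"gene": ["X"], "evidence": ["b"]})
        assert evidence.assemble_core(base).n_core == 0
        more = pd.DataFrame({"gene": ["X", "X"], "evidence": ["b", "g"]})
        assert evidence.assemble_core(more).n_core == 1

    def test_empty_input_gives_empty_core(self):
        core = evidence.assemble_core(pd.DataFrame(columns=["gene", "evidence"]))
        assert core.n_candidates == core.n_core == 0


class TestVennIntersections:
    def test_disjoint_sets_have_empty_intersections(self):
        out = evidence.venn_intersections({"A": {1, 2}, "B": {3, 4}})
        assert out.set_index("region").loc["A&B", "count"] == 0

    def test_subset_relation_empties_private_region(self):
        out = evidence.venn_intersections({"A": {1, 2}, "B": {1, 2, 3}})
        t = out.set_index("region")
        assert t.loc["A", "count"] == 0
        assert t.loc["A&B", "count"] == 2

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(23)
        sets = {name: set(rng.integers(0, 50, size=20)) for name in "ABC"}
        out = evidence.venn_intersections(sets)
        assert out["count"].sum() == len(set().union(*sets.values()))

    def test_composite_core_rule_on_synthetic_freeze_lists(self):
        """Triple intersection plus high-tier-supported freeze genes."""
        shared = {f"S{i}" for i in range(17)}
        extra = {"E1", "E2", "E3"}  # in a freeze and the high-confidence tier
        fg11 = shared | extra | {"F11a", "F11b"}
        fg12 = shared | {"F12a"}
        ot05 = shared | {"O1", "O2"}
        ot075 = extra | set(list(shared)[:5])
        out = evidence.venn_intersections({"FG11": fg11, "FG12": fg12, "OT": ot05})
        t = out.set_index("region")
        assert t.loc["FG11&FG12&OT", "count"] == 17
        core = shared | ((fg11 | fg12) & ot075)
        assert len(core) == 20
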