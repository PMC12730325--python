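"""Gene damage distributions, association tests and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from corewas import burden, simulate
from conftest import brute_force_damage


class TestGeneDamageDistribution:
    @pytest.mark.parametrize("g, s, exp_p0, exp_p1", [
        ([1, 1], [0.5, 0.5], 0.25, 0.5),          # two hets, half damage each
        ([2], [0.9], 0.81, 0.18),                 # one homozygote
        ([0, 0], [0.5, 0.2], 1.0, 0.0),           # no alt alleles
        ([1], [0.0], 0.0, 1.0),                   # one certain event
        ([2], [0.0], 0.0, 0.0),                   # two certain events
        ([1, 1], [0.0, 1.0], 0.0, 1.0),           # certain + benign
    ])
    def test_hand_computed(self, g, s, exp_p0, exp_p1):
        p0, p1 = burden.gene_damage_distribution(g, s)
        assert p0 == pytest.approx(exp_p0, abs=1e-12)
        assert p1 == pytest.approx(exp_p1, abs=1e-12)

    def test_all_synonymous_gene_has_no_damage(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(6, 50))
        p0, p1 = burden.gene_damage_distribution(G, np.ones(6))
        assert np.all(p0 == 1.0) and np.all(p1 == 0.0)

    def test_homozygous_lof_forces_recessive_damage(self):
        p0, p1 = burden.gene_damage_distribution([2, 1], [0.0, 0.7])
        assert 1.0 - p0 - p1 == pytest.approx(1.0)

    @given(st.data())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, data):
        nv = data.draw(st.integers(1, 6))
        g = data.draw(st.lists(st.integers(0, 2), min_size=nv, max_size=nv)
                      .filter(lambda x: sum(x) <= 12))
        s = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=nv, max_size=nv))
        p0, p1 = burden.gene_damage_distribution(g, s)
        b0, b1 = brute_force_damage(g, s)
        assert p0 == pytest.approx(b0, abs=1e-10)
        assert p1 == pytest.approx(b1, abs=1e-10)

    def test_invariants_hold_on_matrix(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(30, 200))
        s = rng.uniform(0, 1, 30)
        p0, p1 = burden.gene_damage_distribution(G, s)
        assert np.all(p0 >= 0) and np.all(p1 >= 0)
        assert np.all(p0 + p1 <= 1 + 1e-12)
        # dominant damage always at least recessive damage
        assert np.all((1 - p0) + 1e-12 >= (1 - p0 - p1))

    def test_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError, match="0, 1"):
            burden.gene_damage_distribution([1], [1.5])

    def test_numerically_stable_for_large_genes(self):
        rng = np.random.default_rng(2)
        nv = 2000
        g = rng.integers(0, 3, size=nv)
        s = rng.uniform(0.2, 1.0, nv)
        p0, p1 = burden.gene_damage_distribution(g, s)
        assert 0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0 and np.isfinite(p0 + p1)


class TestCohensD:
    def test_hand_arithmetic(self):
        assert burden.cohens_d([2, 4], [1, 3]) == pytest.approx(1 / np.sqrt(2))

    def test_identical_groups_give_zero(self):
        assert burden.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_antisymmetric_under_group_swap(self):
        d1 = burden.cohens_d([2, 4, 5], [1, 3, 3])
        d2 = burden.cohens_d([1, 3, 3], [2, 4, 5])
        assert d1 == pytest.approx(-d2)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 2, 40), rng.normal(0, 2, 35)
        d = burden.cohens_d(x, y)
        assert burden.cohens_d(3 * x + 7, 3 * y + 7) == pytest.approx(d)

    def test_zero_pooled_sd_is_undefined(self):
        assert np.isnan(burden.cohens_d([1, 1], [1, 1]))


class TestAdjustMultiple:
    def test_single_p_is_identity(self):
        q, rej = burden.adjust_multiple([0.01], method="bh")
        assert q[0] == pytest.approx(0.01) and rej[0]

    def test_bonferroni_threshold_at_proteome_scale(self):
        # effective per-test threshold 0.05 / 18053 = 2.77e-6
        p = np.full(18053, 0.5)
        p[0], p[1] = 2e-6, 3e-6
        q, rej = burden.adjust_multiple(p, method="bonferroni")
        assert rej[0] and not rej[1]
        assert q[0] == pytest.approx(2e-6 * 18053)

    def test_bh_matches_step_up_definition(self):
        p = np.array([0.001, 0.02, 0.9])
        q, _ = burden.adjust_multiple(p, method="bh")
        m = 3
        expected = [min(p[0] * m / 1, p[1] * m / 2, p[2] * m / 3),
                    min(p[1] * m / 2, p[2] * m / 3), p[2] * m / 3]
        assert q == pytest.approx(expected)

    def test_fixed_threshold_mode(self):
        q, rej = burden.adjust_multiple([1e-8, 1e-6], method="fixed", threshold=5e-7)
        assert list(rej) == [True, False]
        assert list(q) == [1e-8, 1e-6]

    def test_empty_input(self):
        q, rej = burden.adjust_multiple([], method="bh")
        assert q.size == 0 and rej.size == 0


class TestAssociateGene:
    def test_constant_score_is_flagged_not_raised(self):
        rng = np.random.default_rng(4)
        n = 200
        scores = burden.GeneScoreSet("flat", np.ones(n), np.zeros(n))
        y = rng.integers(0, 2, n)
        res = burden.associate_gene(scores, y, rng.normal(size=(n, 2)))
        assert not res.ok and np.isnan(res.p_combined)

    def test_requires_cases_and_controls(self):
        scores = burden.GeneScoreSet("g", np.linspace(0, 1, 10), np.zeros(10))
        with pytest.raises(ValueError, match="case"):
            burden.associate_gene(scores, np.zeros(10), np.ones((10, 1)))

    def test_planted_dominant_gene_is_recovered(self, small_cohort):
        c = small_cohort
        sets = burden.gene_scores(c.variants, c.genotypes)
        res = burden.associate_genes(sets, c.phenotype, c.covariates)
        best = res.sort_values("p_combined").iloc[0]
        assert best["gene"] == "g0003"
        assert best["mode"] == "dominant"
        # risk gene: damage associates with case status => negative z on
        # the effect score and negative Cohen's d
        assert best["z_dom"] < 0 and best["d_dom"] < 0

    def test_carriers_enriched_in_cases_across_seeds(self):
        wins = 0
        for seed in range(20):
            cfg = simulate.PopulationConfig(n_individuals=400, n_genes=6, seed=seed)
            truth = simulate.SimTruth(
                (simulate.RiskGene("g0001", "dominant", 2.0),))
            c = simulate.simulate_cohort(cfg, truth)
            sets = burden.gene_scores(c.variants, c.genotypes)
            dmg = sets["g0001"].dom_damage
            carrier = dmg > 0.2
            y = c.phenotype.astype(bool)
            wins += carrier[y].mean() > carrier[~y].mean()
        assert wins >= 17

    def test_null_combined_pvalues_are_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(9)
        cfg = simulate.PopulationConfig(n_individuals=600, n_genes=4, seed=9)
        ps = []
        for _ in range(60):
            c = simulate.simulate_cohort(cfg, rng=rng)
            sets = burden.gene_scores(c.variants, c.genotypes)
            res = burden.associate_genes(sets, c.phenotype, c.covariates)
            ps.extend(res.loc[res["ok"], "p_combined"].dropna())
        assert stats.kstest(ps, "uniform").pvalue > 0.01
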