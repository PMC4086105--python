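"""Split-half overlap, randomized controls, KS and rank-sum statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from phylink import (
    GeneSetCollection,
    compare_evo_vs_combined,
    evaluate_method,
    ks_two_sample,
    randomized_control,
    split_half_overlap,
    wilcoxon_rank_sum,
)
from phylink.ranking import RankingConfig


def collection(**sets):
    return GeneSetCollection(sets={t: frozenset(g) for t, g in sets.items()})


class TestSplitHalfOverlap:
    def test_identical_term_sets_give_one(self):
        ann = collection(T1={"a", "b", "c", "d"})
        assert split_half_overlap(["a", "b", "c", "d"], ann, 0) == 1.0

    def test_disjoint_term_sets_give_zero(self, rng):
        # every split puts the two genes apart, and their terms are disjoint
        ann = collection(T1={"a"}, T2={"b"})
        assert split_half_overlap(["a", "b"], ann, rng) == 0.0

    def test_partial_overlap_is_jaccard(self):
        # whatever the split of [x, y], T1={A,B} vs T2={B,C}: |∩|=1, |∪|=3
        ann = collection(A={"x"}, B={"x", "y"}, C={"y"})
        for seed in range(5):
            assert split_half_overlap(["x", "y"], ann, seed) == pytest.approx(1 / 3)

    def test_unannotated_genes_and_empty_terms_score_zero(self):
        ann = collection(T1={"other"})
        assert split_half_overlap(["a", "b"], ann, 0) == 0.0
        assert split_half_overlap([], ann, 0) == 0.0

    def test_over_smaller_statistic(self):
        # halves {x} and {y}: T1={A,B}, T2={B}; over-smaller = 1/1
        ann = collection(A={"x"}, B={"x", "y"})
        for seed in range(5):
            assert split_half_overlap(["x", "y"], ann, seed,
                                      statistic="over_smaller") == 1.0

    def test_odd_list_splits_into_ceil_and_floor_halves(self):
        # 5 genes, one term per gene marking its half: term-set sizes must be 3 and 2
        ann = collection(**{f"T{i}": {f"g{i}"} for i in range(5)})
        genes = [f"g{i}" for i in range(5)]
        for seed in range(10):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(5)
            t1 = {f"T{perm[k]}" for k in range(3)}
            t2 = {f"T{perm[k]}" for k in range(3, 5)}
            # private terms: Jaccard must be 0 with |T1|=3, |T2|=2
            assert len(t1) == 3 and len(t2) == 2
            assert split_half_overlap(genes, ann, np.random.default_rng(seed)) == 0.0

    def test_seeded_split_is_reproducible(self):
        ann = collection(A={"a", "b"}, B={"c", "d"}, C={"a", "c"})
        genes = ["a", "b", "c", "d"]
        vals = {split_half_overlap(genes, ann, 42) for _ in range(5)}
        assert len(vals) == 1


class TestQueryTermOverlap:
    def test_partner_with_identical_terms_scores_one(self):
        from phylink import query_term_overlap

        ann = collection(T1={"q", "a"}, T2={"q", "a"})
        assert query_term_overlap("q", ["a"], ann) == 1.0

    def test_mean_over_mixed_list(self):
        from phylink import query_term_overlap

        # q: {T1}; a: {T1} -> 1; b: {T2} -> 0; c: unannotated -> 0
        ann = collection(T1={"q", "a"}, T2={"b"})
        assert query_term_overlap("q", ["a", "b", "c"], ann) == pytest.approx(1 / 3)

    def test_empty_list_and_unannotated_query_score_zero(self):
        from phylink import query_term_overlap

        ann = collection(T1={"a"})
        assert query_term_overlap("q", [], ann) == 0.0
        assert query_term_overlap("q", ["a"], ann) == 0.0


class TestRandomizedControl:
    def test_single_set_is_a_permutation_of_itself(self):
        sets = {"q": ["a", "b", "c", "d"]}
        out = randomized_control(sets, 0)
        assert sorted(out["q"]) == ["a", "b", "c", "d"]

    def test_global_multiset_and_cardinalities_conserved(self, rng):
        sets = {f"q{i}": [f"g{rng.integers(100)}" for _ in range(rng.integers(3, 9))]
                for i in range(20)}
        out = randomized_control(sets, rng)
        assert sorted(g for s in out.values() for g in s) == \
               sorted(g for s in sets.values() for g in s)
        assert {q: len(s) for q, s in out.items()} == {q: len(s) for q, s in sets.items()}

    def test_pool_size_matches_design(self):
        """25 sets x 5 genes pool and re-deal exactly 125 slots."""
        sets = {f"q{i}": [f"q{i}_g{j}" for j in range(5)] for i in range(25)}
        out = randomized_control(sets, 1)
        assert sum(len(s) for s in out.values()) == 125


class TestKsTwoSample:
    def test_identical_samples_give_zero_d(self):
        a = [0.1, 0.4, 0.4, 0.9]
        d, p = ks_two_sample(a, a)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_non_overlapping_supports_give_d_one(self):
        d, _ = ks_two_sample([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert d == 1.0

    def test_hand_enumerated_interleaved_case(self):
        d, _ = ks_two_sample([0.1, 0.5], [0.3, 0.7])
        assert d == pytest.approx(0.5)

    def test_matches_brute_force_ecdf_scan(self, rng):
        """D equals the max ECDF difference at every pooled data point (n<=50)."""
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(5, 51)))
            b = rng.normal(loc=rng.uniform(-1, 1), size=int(rng.integers(5, 51)))
            d, _ = ks_two_sample(a, b)
            pooled = np.concatenate([a, b])
            brute = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in pooled
            )
            assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestWilcoxonRankSum:
    def test_hand_enumerated_ranks(self):
        w, _ = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 3.0

    def test_identical_samples_give_p_near_one(self):
        a = [0.2, 0.5, 0.7, 0.9]
        w, p = wilcoxon_rank_sum(a, a)
        assert p == pytest.approx(1.0)

    def test_rank_conservation(self, rng):
        """W(a,b) + W(b,a) = N(N+1)/2 for pooled size N, ties included."""
        for _ in range(20):
            a = np.round(rng.normal(size=int(rng.integers(2, 30))), 1)
            b = np.round(rng.normal(size=int(rng.integers(2, 30))), 1)
            wab, _ = wilcoxon_rank_sum(a, b)
            wba, _ = wilcoxon_rank_sum(b, a)
            n = len(a) + len(b)
            assert wab + wba == pytest.approx(n * (n + 1) / 2)

    def test_p_value_cross_checked_against_mann_whitney(self, rng):
        """W - n_a(n_a+1)/2 is Mann-Whitney U; asymptotic p-values agree."""
        a = rng.normal(size=40)
        b = rng.normal(loc=0.5, size=35)
        w, p = wilcoxon_rank_sum(a, b)
        mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert w - 40 * 41 / 2 == pytest.approx(mw.statistic)
        assert p == pytest.approx(mw.pvalue, rel=1e-9)

    def test_degenerate_all_equal_values(self):
        w, p = wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0


class TestEvaluateMethod:
    def test_method_identical_to_control_distribution_gives_small_d(self):
        """Sets already random: method and control fractions coincide in law.

        With the same genes re-dealt, D stays far from 1 (exact equality of
        the two samples is not required, only distributional agreement).
        """
        rng = np.random.default_rng(5)
        pool = [f"g{i}" for i in range(200)]
        ann = GeneSetCollection(sets={
            f"T{j}": frozenset(rng.choice(pool, size=12, replace=False))
            for j in range(30)
        })
        sets = {f"q{i}": list(rng.choice(pool, size=10, replace=False))
                for i in range(60)}
        res = evaluate_method(sets, ann, rng_seed=6)
        assert res.ks_p > 0.01
        assert res.n_queries == 60

    def test_planted_modules_separate_from_control(self, small_sim):
        """Coherent result sets stochastically dominate the shuffled control."""
        from phylink import distances_to_query, correlations_to_query, rank_candidates

        config, matrix, membership, expr, annotations = small_sim
        queries = sorted(membership)[:20]
        cfg = RankingConfig(top_n=10)
        sets = {}
        for q in queries:
            d = distances_to_query(q, matrix)
            c = correlations_to_query(q, expr)
            sets[q] = [r.gene for r in rank_candidates(q, d, c, cfg)]
        res = evaluate_method(sets, annotations, rng_seed=9)
        assert res.ks_D > 0
        assert res.ks_p < 0.01
        mean_m = np.mean([s.fraction for s in res.method_fractions])
        mean_c = np.mean([s.fraction for s in res.control_fractions])
        assert mean_m > mean_c

    def test_fixed_seed_is_bit_reproducible(self, small_sim):
        _, _, membership, _, annotations = small_sim
        rng = np.random.default_rng(3)
        genes = sorted(membership)
        sets = {f"q{i}": list(rng.choice(genes, size=8, replace=False))
                for i in range(15)}
        r1 = evaluate_method(sets, annotations, rng_seed=77)
        r2 = evaluate_method(sets, annotations, rng_seed=77)
        assert r1.ks_D == r2.ks_D and r1.ks_p == r2.ks_p
        assert [s.fraction for s in r1.method_fractions] == \
               [s.fraction for s in r2.method_fractions]


class TestCompareEvoVsCombined:
    def test_identical_rankings_give_identical_scores(self, small_sim):
        """When every pair has the same r, both modes produce the same
        ordering (ties fall back to gene id) and, since the split seed is
        shared per query, the same score sample."""
        import pandas as pd

        from phylink import ExpressionMatrix

        config, matrix, membership, expr, annotations = small_sim
        # every gene shares one expression row -> r = 1.0 for all pairs
        row = np.linspace(1.0, 9.0, 20)
        flat = ExpressionMatrix(
            values=pd.DataFrame(
                np.tile(row, (len(matrix.genes), 1)), index=matrix.genes,
                columns=[f"s{j}" for j in range(20)],
            ),
            normalization_state="log2",
        )
        queries = sorted(membership)[:6]
        cfg = RankingConfig(top_n=15)
        res = compare_evo_vs_combined(
            queries, matrix, flat, annotations, cfg, rng_seed=1
        )
        assert res.scores_evo_only == res.scores_combined
        assert "rank-sum" in res.convention

    def test_uninformative_expression_shows_no_systematic_direction(self):
        """With rho=0 (pure-noise expression) and min_corr=0, the combined
        and evolution-only scores share a distribution: the rank-sum test
        should reject at about its nominal rate over repeated worlds."""
        from phylink import (
            SimulationConfig,
            correlations_to_query,
            distances_to_query,
            simulate_annotations,
            simulate_expression,
            simulate_profiles,
        )
        from phylink.simulate import gene_roster

        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg_sim = SimulationConfig(
                n_species=40, n_genes=60, n_modules=4, module_size=5,
                n_samples=40, module_expression_rho=0.0, seed=1000 + seed,
            )
            matrix, membership = simulate_profiles(cfg_sim)
            expr = simulate_expression(cfg_sim, membership)
            # annotations decoupled from the planted modules: assign module
            # labels to a random permutation of genes, so neither ranking
            # mode carries annotation signal and the null is exact
            perm_rng = np.random.default_rng(2000 + seed)
            shuffled = list(perm_rng.permutation(matrix.genes))
            ann_membership = {shuffled[i]: m
                              for i, m in enumerate(membership.values())}
            bg = [g for g in matrix.genes if g not in ann_membership]
            ann = simulate_annotations(ann_membership, background_genes=bg,
                                       rng_seed=2000 + seed)
            queries = sorted(membership)
            cfg = RankingConfig(min_corr=0.0, top_n=10)
            res = compare_evo_vs_combined(
                queries, matrix, expr, ann, cfg, rng_seed=3000 + seed
            )
            if res.wilcoxon_p < 0.05:
                rejections += 1
        # Binomial(20, 0.05): P(X >= 5) < 4e-4
        assert rejections <= 4

    def test_coexpression_improves_overlap_on_planted_modules(self, small_sim):
        config, matrix, membership, expr, annotations = small_sim
        queries = sorted(membership)
        cfg = RankingConfig(top_n=15)
        res = compare_evo_vs_combined(
            queries, matrix, expr, annotations, cfg, rng_seed=21
        )
        assert np.mean(res.scores_combined) > np.mean(res.scores_evo_only)
        assert res.wilcoxon_p < 0.05
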