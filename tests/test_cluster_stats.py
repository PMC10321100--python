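"""Pointwise tests, cluster construction and the permutation machinery."""

import numpy as np
import pytest
from scipy import stats

from eureka_eeg.cluster_stats import (
    build_clusters,
    permutation_test,
    pointwise_stat,
    rank_sum,
)


class TestPointwiseStat:
    def test_identical_inputs_give_zero_statistic(self, rng):
        a = rng.standard_normal((6, 4, 5))
        stat, p, tests = pointwise_stat(a, a.copy())
        assert np.allclose(stat, 0.0)

    def test_constant_shift_sign_matches(self, rng):
        a = rng.standard_normal((10, 3, 4)) + 2.0
        b = rng.standard_normal((10, 3, 4))
        stat, _, _ = pointwise_stat(a, b, gate_normality=False)
        assert np.all(stat > 0)

    def test_hand_computed_five_pair_t(self):
        a = np.array([2.0, 4.0, 3.0, 5.0, 6.0])[:, None]
        b = np.array([1.0, 1.0, 2.0, 2.0, 3.0])[:, None]
        d = (a - b).ravel()
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        stat, p, tests = pointwise_stat(a, b, gate_normality=False)
        assert stat[0] == pytest.approx(expected, rel=1e-12)
        assert tests[0] == "t"

    def test_normality_gate_switches_to_wilcoxon(self, rng):
        # heavy-tailed differences: Shapiro should reject at most coordinates
        a = rng.standard_cauchy((30, 6)) * 100
        b = rng.standard_normal((30, 6))
        _, _, tests = pointwise_stat(a, b)
        assert np.sum(tests == "wilcoxon") >= 4

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            pointwise_stat(rng.standard_normal((2, 3)), rng.standard_normal((2, 3)))


class TestBuildClusters:
    adjacency = np.array(
        [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool
    )  # chain a-b-c

    def test_toy_chain_clustering_by_hand(self):
        # suprathreshold: {A@t1, B@t1, B@t2, C@t5} -> {A1,B1,B2} and {C5}
        stat = np.zeros((3, 6))
        stat[0, 1] = stat[1, 1] = stat[1, 2] = stat[2, 5] = 3.0
        clusters = build_clusters(stat, threshold=2.0, adjacency=self.adjacency)
        member_sets = sorted(sorted(c.members) for c in clusters)
        assert member_sets == [[(0, 1), (1, 1), (1, 2)], [(2, 5)]]
        assert {round(c.stat_sum, 9) for c in clusters} == {9.0, 3.0}

    def test_non_adjacent_channels_same_time_stay_separate(self):
        stat = np.zeros((3, 4))
        stat[0, 2] = stat[2, 2] = 5.0  # a and c are not adjacent
        clusters = build_clusters(stat, 2.0, self.adjacency)
        assert len(clusters) == 2

    def test_consecutive_bins_same_channel_merge(self):
        stat = np.zeros((3, 4))
        stat[1, 1] = stat[1, 2] = 5.0
        clusters = build_clusters(stat, 2.0, self.adjacency)
        assert len(clusters) == 1 and clusters[0].stat_sum == 10.0

    def test_positive_and_negative_kept_separate(self):
        stat = np.zeros((1, 5))
        stat[0, 1], stat[0, 2] = 4.0, -4.0
        clusters = build_clusters(stat, 2.0, None)
        assert sorted(c.stat_sum for c in clusters) == [-4.0, 4.0]

    def test_empty_suprathreshold_set_is_valid(self):
        assert build_clusters(np.zeros((2, 4)), 2.0, None) == []

    def test_matches_brute_force_components_on_random_graphs(self, rng):
        # oracle: grow components by repeated neighbour expansion
        for _ in range(10):
            n = 8
            adj = rng.random((n, n)) < 0.25
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            stat = rng.standard_normal((n, 6)) * 2
            clusters = build_clusters(stat, 1.5, adj)
            mask = stat > 1.5
            # brute force on the positive side
            nodes = {(s, t) for s, t in zip(*np.nonzero(mask))}
            comps = []
            while nodes:
                frontier = {nodes.pop()}
                comp = set()
                while frontier:
                    s, t = frontier.pop()
                    comp.add((s, t))
                    for u, v in list(nodes):
                        if (u == s and abs(v - t) == 1) or (v == t and adj[u, s]):
                            nodes.remove((u, v))
                            frontier.add((u, v))
                comps.append(comp)
            got = sorted(
                sorted(c.members) for c in clusters if c.stat_sum > 0
            )
            assert got == sorted(sorted(c) for c in comps)


class TestPermutationTest:
    def test_same_seed_identical_p_values(self, rng):
        a = rng.standard_normal((8, 4, 10))
        b = rng.standard_normal((8, 4, 10))
        r1 = permutation_test(a, b, n_perm=200, seed=5)
        r2 = permutation_test(a, b, n_perm=200, seed=5)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_p_values_never_exactly_zero(self, rng):
        a = rng.standard_normal((10, 2, 6)) + 5.0  # overwhelming effect
        b = rng.standard_normal((10, 2, 6))
        res = permutation_test(a, b, n_perm=200, seed=0)
        assert all(c.p_value >= 1 / 201 for c in res.clusters)
        assert res.significant

    def test_invariant_to_relabeling_both_groups(self, rng):
        a = rng.standard_normal((8, 3, 8))
        b = rng.standard_normal((8, 3, 8))
        r_ab = permutation_test(a, b, n_perm=300, seed=2)
        r_ba = permutation_test(b, a, n_perm=300, seed=2)
        assert sorted(round(c.p_value, 12) for c in r_ab.clusters) == sorted(
            round(c.p_value, 12) for c in r_ba.clusters
        )

    def test_wilcoxon_variant_runs_and_flags_large_effect(self, rng):
        a = rng.standard_normal((12, 1, 8)) + 3.0
        b = rng.standard_normal((12, 1, 8))
        res = permutation_test(a, b, n_perm=300, seed=0, stat="wilcoxon")
        assert res.significant

    def test_degenerate_constant_data_yields_no_clusters(self):
        a = np.ones((6, 2, 5))
        res = permutation_test(a, a.copy(), n_perm=150, seed=0)
        assert res.clusters == []

    def test_small_n_perm_warns(self, rng):
        a = rng.standard_normal((6, 1, 4))
        with pytest.warns(UserWarning):
            permutation_test(a, a.copy(), n_perm=50, seed=0)


class TestRankSum:
    def test_identical_samples_not_significant(self):
        x = np.arange(1.0, 9.0)
        z, p, _ = rank_sum(x, x.copy())
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_toy_extreme_case_exact_p(self):
        z, p, medians = rank_sum([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)  # most extreme attainable for n = 3, 3
        assert medians == (2.0, 11.0)

    def test_matches_scipy_asymptotic_for_large_samples(self, rng):
        a = rng.lognormal(0.12, 0.5, 300)
        b = rng.lognormal(0.69, 0.5, 300)
        z, p, _ = rank_sum(a, b)
        z_ref, p_ref = stats.ranksums(a, b)
        assert z == pytest.approx(z_ref)
        assert p == pytest.approx(p_ref)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])
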