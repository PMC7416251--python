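import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterlab.exceptions import ConfigError, UndefinedIndexError
from clusterlab.kmeans import best_of_restarts
from clusterlab.synthetic import MixtureSpec, make_mixture
from clusterlab.validity import (accuracy_matched, dunn_index, f_measure,
                                 hubert_gamma, majority_vote, mi_and_vi,
                                 pair_counts, rand_and_ari, rpt, select_k,
                                 silhouette_mean)
from conftest import random_partition_pair
from oracles import (naive_accuracy, naive_ari, naive_dunn, naive_f_measure,
                     naive_hubert, naive_mi_vi, naive_pair_counts, naive_rand,
                     naive_silhouette)

U_TOY = np.array([1, 1, 1, 2, 2, 2])
V_TOY = np.array([1, 1, 2, 2, 2, 2])


class TestSilhouette:
    def test_four_point_hand_value(self):
        X = np.array([0.0, 0.1, 10.0, 10.1]).reshape(-1, 1)
        labels = np.array([0, 0, 1, 1])
        expect = (2 * (9.95 / 10.05) + 2 * (9.85 / 9.95)) / 4
        assert abs(silhouette_mean(X, labels) - expect) < 1e-12
        assert abs(expect - 0.990) < 1e-3

    def test_coincident_pairs_give_one(self):
        X = np.array([[0.0], [0.0], [50.0], [50.0]])
        assert silhouette_mean(X, np.array([0, 0, 1, 1])) == 1.0

    def test_single_cluster_undefined(self, rng):
        with pytest.raises(UndefinedIndexError):
            silhouette_mean(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))

    def test_singleton_contributes_zero(self):
        X = np.array([[0.0], [1.0], [2.0]])
        labels = np.array([0, 0, 1])
        # s(singleton)=0; points 0,1: a=1, b = mean dist to cluster1
        s0 = (2.0 - 1.0) / 2.0
        s1 = (1.0 - 1.0) / 1.0
        expect = (s0 + s1 + 0.0) / 3
        assert abs(silhouette_mean(X, labels) - expect) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        g = np.random.default_rng(seed)
        X = g.normal(size=(25, 3))
        labels = g.integers(0, 3, size=25)
        if len(set(labels.tolist())) < 2:
            return
        assert abs(silhouette_mean(X, labels) - naive_silhouette(X, labels)) < 1e-10

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_score
        X = rng.normal(size=(40, 3))
        labels = rng.integers(0, 4, size=40)
        assert abs(silhouette_mean(X, labels) - silhouette_score(X, labels)) < 1e-10


class TestDunn:
    def test_hand_value(self):
        X = np.array([0.0, 0.1, 10.0, 10.1]).reshape(-1, 1)
        assert abs(dunn_index(X, np.array([0, 0, 1, 1])) - 99.0) < 1e-9

    def test_translation_scales_linearly(self):
        base = np.array([[0.0], [1.0]])
        for t in (10.0, 20.0, 40.0):
            X = np.vstack([base, base + t])
            labels = np.array([0, 0, 1, 1])
            assert abs(dunn_index(X, labels) - (t - 1.0) / 1.0) < 1e-9

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_naive_oracle(self, seed):
        g = np.random.default_rng(seed)
        X = g.normal(size=(20, 2))
        labels = g.integers(0, 3, size=20)
        if len(set(labels.tolist())) < 2:
            return
        assert abs(dunn_index(X, labels) - naive_dunn(X, labels)) < 1e-10

    def test_point_mass_clusters_inf(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert dunn_index(X, np.array([0, 0, 1, 1])) == math.inf


class TestRpt:
    def test_b_too_small(self, blobs3):
        with pytest.raises(ConfigError):
            rpt(blobs3.X, blobs3.labels, B=5, seed=0)

    def test_stable_clustering_near_two_si(self, blobs3):
        si = silhouette_mean(blobs3.X, blobs3.labels)
        val = rpt(blobs3.X, blobs3.labels, B=15, seed=0)
        assert abs(val - 2 * si) < 0.02 * abs(si)

    def test_ratio_bounds(self, rng):
        X = rng.normal(size=(40, 2))
        labels = best_of_restarts(X, 3, restarts=5, seed=0).labels
        si = silhouette_mean(X, labels)
        val = rpt(X, labels, B=12, seed=1)
        assert 1.0 < val / si <= 2.0

    def test_unstable_labels_only_chance_agreement(self, rng):
        # arbitrary labels on structureless noise agree with refits only by
        # chance, so the stability factor (1 + S_bar) sits mid-band
        X = rng.normal(size=(60, 2))
        labels = rng.integers(0, 3, size=60)
        si = silhouette_mean(X, labels)
        assert si != 0
        stability = rpt(X, labels, B=15, seed=2) / si  # = 1 + S_bar
        assert 1.2 < stability < 1.85


class TestPairCounts:
    def test_toy_hand_count(self):
        assert pair_counts(U_TOY, V_TOY) == (4, 2, 3, 6)

    def test_identical_partitions(self):
        a, b, c, d = pair_counts(U_TOY, U_TOY)
        assert b == 0 and c == 0

    def test_degenerate_single_cluster(self):
        v = np.ones(6, dtype=int)
        a, b, c, d = pair_counts(U_TOY, v)
        assert d == 0 and c == 9  # all 3*3 cross-class pairs joined only in v

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pair_counts(np.array([0, 1]), np.array([0, 1, 2]))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_and_sums(self, seed):
        g = np.random.default_rng(seed)
        u, v = random_partition_pair(g)
        got = pair_counts(u, v)
        assert got == naive_pair_counts(u, v)
        assert sum(got) == len(u) * (len(u) - 1) // 2


class TestRandAri:
    def test_toy_values(self):
        ri, ari = rand_and_ari(U_TOY, V_TOY)
        assert abs(ri - 10 / 15) < 1e-12
        assert abs(ari - 1.2 / 3.7) < 1e-12

    def test_identical(self):
        ri, ari = rand_and_ari(U_TOY, U_TOY)
        assert ri == 1.0 and ari == 1.0

    def test_chance_level_near_zero(self):
        vals = []
        for s in range(100):
            g = np.random.default_rng(s)
            u = g.integers(0, 4, 200)
            v = g.integers(0, 4, 200)
            vals.append(rand_and_ari(u, v)[1])
        assert abs(np.mean(vals)) < 0.02

    def test_trivial_partitions_defined(self):
        ones = np.ones(5, dtype=int)
        ri, ari = rand_and_ari(ones, ones)
        assert ri == 1.0 and ari == 1.0

    def test_matches_sklearn_ari(self, rng):
        from sklearn.metrics import adjusted_rand_score
        for s in range(20):
            g = np.random.default_rng(s)
            u, v = random_partition_pair(g)
            assert abs(rand_and_ari(u, v)[1] - adjusted_rand_score(u, v)) < 1e-10


class TestAccuracy:
    def test_toy_value(self):
        assert abs(accuracy_matched(U_TOY, V_TOY) - 5 / 6) < 1e-12

    def test_permutation_invariance(self, rng):
        u, v = random_partition_pair(rng)
        perm = rng.permutation(int(v.max()) + 1)
        assert accuracy_matched(u, v) == accuracy_matched(u, perm[v])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_permutation_oracle(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(6, 30))
        u = g.integers(0, int(g.integers(2, 6)), size=n)
        v = g.integers(0, int(g.integers(2, 6)), size=n)
        assert abs(accuracy_matched(u, v) - naive_accuracy(list(u), list(v))) < 1e-12


class TestFMeasure:
    def test_identity(self):
        assert f_measure(U_TOY, U_TOY) == 1.0

    def test_toy_hand_value(self):
        expect = 0.5 * 0.8 + 0.5 * (6 / 7)
        assert abs(f_measure(U_TOY, V_TOY) - expect) < 1e-12

    def test_single_class_closed_form(self, rng):
        # one class: F = max over clusters of 2*size_j/(size_j + n)
        v = rng.integers(0, 3, size=30)
        u = np.zeros(30, dtype=int)
        sizes = np.bincount(v)
        expect = max(2 * s / (s + 30) for s in sizes if s > 0)
        assert abs(f_measure(u, v) - expect) < 1e-12

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive(self, seed):
        g = np.random.default_rng(seed)
        u, v = random_partition_pair(g)
        assert abs(f_measure(u, v) - naive_f_measure(list(u), list(v))) < 1e-12


class TestHubert:
    def test_toy_value(self):
        expect = 18 / math.sqrt(54 * 56)
        assert abs(hubert_gamma(U_TOY, V_TOY) - expect) < 1e-12

    def test_identity(self):
        assert abs(hubert_gamma(U_TOY, U_TOY) - 1.0) < 1e-12

    def test_trivial_partition_undefined(self):
        with pytest.raises(UndefinedIndexError):
            hubert_gamma(U_TOY, np.ones(6, dtype=int))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_naive(self, seed):
        g = np.random.default_rng(seed)
        u, v = random_partition_pair(g, n_max=40)
        expect = naive_hubert(list(u), list(v))
        if expect is None:
            return
        assert abs(hubert_gamma(u, v) - expect) < 1e-10


class TestMiVi:
    def test_toy_values(self):
        mi, vi = mi_and_vi(U_TOY, V_TOY)
        hu = math.log(2)
        hv = -(1 / 3) * math.log(1 / 3) - (2 / 3) * math.log(2 / 3)
        huv = -(1 / 3) * math.log(1 / 3) - (1 / 6) * math.log(1 / 6) - 0.5 * math.log(0.5)
        assert abs(mi - (hu + hv - huv)) < 1e-12
        assert abs(vi - (hu + hv - 2 * (hu + hv - huv))) < 1e-12
        assert abs(mi - 0.3183) < 5e-4
        assert abs(vi - 0.6931) < 5e-4

    def test_identity_metric(self):
        _, vi = mi_and_vi(U_TOY, U_TOY)
        assert vi == 0.0

    def test_triangle_inequality(self):
        for s in range(100):
            g = np.random.default_rng(s)
            n = int(g.integers(5, 40))
            u, v, w = (g.integers(0, 4, n) for _ in range(3))
            _, uv = mi_and_vi(u, v)
            _, vw = mi_and_vi(v, w)
            _, uw = mi_and_vi(u, w)
            assert uw <= uv + vw + 1e-10

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive(self, seed):
        g = np.random.default_rng(seed)
        u, v = random_partition_pair(g)
        mi, vi = mi_and_vi(u, v)
        emi, evi = naive_mi_vi(list(u), list(v))
        assert abs(mi - emi) < 1e-10 and abs(vi - evi) < 1e-10


class TestPermutationInvariance:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_all_indices_invariant_to_relabelling(self, seed):
        g = np.random.default_rng(seed)
        u, v = random_partition_pair(g, n_max=30)
        perm_u = g.permutation(int(u.max()) + 1)
        perm_v = g.permutation(int(v.max()) + 1)
        pu, pv = perm_u[u], perm_v[v]
        assert pair_counts(u, v) == pair_counts(pu, pv)
        assert rand_and_ari(u, v) == rand_and_ari(pu, pv)
        assert accuracy_matched(u, v) == accuracy_matched(pu, pv)
        np.testing.assert_allclose(mi_and_vi(u, v), mi_and_vi(pu, pv), atol=1e-12)


class TestSelectK:
    def test_three_blobs_unanimous(self, blobs3):
        sel = select_k(blobs3.X, k_range=(2, 6), gap_B=10, seed=0)
        assert sel.k_elbow == sel.k_gap == sel.k_silhouette == 3
        assert sel.k_final == 3 and not sel.tie

    def test_median_rule(self):
        k, tie = majority_vote(2, 3, 4)
        assert k == 3 and tie

    def test_majority_rule(self):
        k, tie = majority_vote(4, 2, 4)
        assert k == 4 and not tie

    def test_range_clipped(self, rng):
        X = rng.normal(size=(8, 2))
        sel = select_k(X, k_range=(2, 15), gap_B=10, seed=0)
        assert sel.search_range[1] == 7
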