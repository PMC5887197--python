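import math

import numpy as np
import pytest

import phyloclust as pc
from phyloclust.clustering import Partition
from phyloclust.tree_splits import DistanceMatrix
from phyloclust.validity import global_medoid, score_partition

from conftest import two_cluster_partitions


class TestSilhouetteComponents:
    def test_a_includes_self_term_in_denominator(self, micro):
        d, p = micro  # cluster {0,1} with d=2: a = (0+2)/2 = 1
        assert pc.a_value(0, p, d) == 1.0

    def test_a_singleton_zero(self, micro):
        d, _ = micro
        p = Partition(labels=np.array([0, 1, 1, 1]), medoids=(0, 2), K=2)
        assert pc.a_value(0, p, d) == 0.0

    def test_b_constant_cross_distance(self, micro):
        d, p = micro
        assert pc.b_value(0, p, d) == 8.0

    def test_b_takes_minimum_over_foreign_clusters(self):
        v = np.zeros((6, 6), dtype=np.int64)
        v[np.ix_([0, 1], [2, 3])] = 8; v[np.ix_([2, 3], [0, 1])] = 8
        v[np.ix_([0, 1], [4, 5])] = 6; v[np.ix_([4, 5], [0, 1])] = 6
        v[np.ix_([2, 3], [4, 5])] = 7; v[np.ix_([4, 5], [2, 3])] = 7
        d = DistanceMatrix(values=v, kind="rf", n_leaves=8)
        p = Partition(labels=np.array([0, 0, 1, 1, 2, 2]), medoids=(0, 2, 4), K=3)
        assert pc.b_value(0, p, d) == 6.0

    def test_b_requires_two_clusters(self, micro):
        d, _ = micro
        p = Partition(labels=np.zeros(4, dtype=int), medoids=(0,), K=1)
        with pytest.raises(ValueError):
            pc.b_value(0, p, d)


class TestSilhouette:
    def test_micro_hand_trace(self, micro):
        d, p = micro  # each element: (8-1)/8 = 0.875
        score = pc.silhouette_index(p, d)
        assert score.value == 0.875 and score.per_cluster == [0.875, 0.875]

    def test_perfectly_separated_identical_clusters(self):
        v = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]])
        d = DistanceMatrix(values=v.astype(np.int64), kind="rf", n_leaves=6)
        p = Partition(labels=np.array([0, 0, 1, 1]), medoids=(0, 2), K=2)
        assert pc.silhouette_index(p, d).value == 1.0

    def test_degenerate_split_of_identical_trees_scores_zero(self):
        d = DistanceMatrix(values=np.zeros((4, 4), dtype=np.int64),
                           kind="rf", n_leaves=6)
        p = Partition(labels=np.array([0, 0, 1, 1]), medoids=(0, 2), K=2)
        assert pc.silhouette_index(p, d).value == 0.0

    def test_bounds_on_random_partitions(self):
        rng = np.random.default_rng(31)
        ts = pc.TreeSet([pc.random_binary_tree(8, rng=rng) for _ in range(20)])
        d = pc.pairwise_rf_matrix(ts)
        for _ in range(50):
            K = int(rng.integers(2, 6))
            labels = np.concatenate([np.arange(K), rng.integers(0, K, 20 - K)])
            rng.shuffle(labels)
            part = pc.assign_to_medoids(
                tuple(int(np.flatnonzero(labels == k)[0]) for k in range(K)), d)
            sh = pc.silhouette_index(part, d).value
            assert -1.0 <= sh <= 1.0
            assert pc.ch_index(part, d).value >= 0.0


class TestCH:
    def test_ssw_equals_objective(self, micro):
        d, p = micro
        assert pc.ss_w(p, d) == pc.objective_med(p, d) == 4

    def test_ssw_equals_objective_random_partitions(self):
        rng = np.random.default_rng(41)
        ts = pc.TreeSet([pc.random_binary_tree(8, rng=rng) for _ in range(15)])
        d = pc.pairwise_rf_matrix(ts)
        for _ in range(100):
            meds = tuple(sorted(int(x) for x in rng.choice(15, 3, replace=False)))
            try:
                part = pc.assign_to_medoids(meds, d)
            except ValueError:
                continue  # duplicate-topology medoids emptied a cluster
            part = Partition(labels=part.labels,
                             medoids=pc.update_medoids(part, d), K=3)
            assert pc.ss_w(part, d) == pc.objective_med(part, d)

    def test_ssb_hand_trace(self, micro):
        d, p = micro  # global medoid = tree 0 (total 18, tie to smallest index)
        assert global_medoid(d) == 0
        assert pc.ss_b(p, d) == 2 * 0 + 2 * 8 == 16

    def test_ch_micro(self, micro):
        d, p = micro
        assert pc.ch_index(p, d).value == (16 / 4) * ((4 - 2) / (2 - 1)) == 8

    def test_perfect_separation_infinite(self):
        v = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]])
        d = DistanceMatrix(values=v.astype(np.int64), kind="rf", n_leaves=6)
        p = Partition(labels=np.array([0, 0, 1, 1]), medoids=(0, 2), K=2)
        assert math.isinf(pc.ch_index(p, d).value)

    def test_all_identical_scores_zero(self):
        d = DistanceMatrix(values=np.zeros((4, 4), dtype=np.int64),
                           kind="rf", n_leaves=6)
        p = Partition(labels=np.array([0, 0, 1, 1]), medoids=(0, 2), K=2)
        assert pc.ch_index(p, d).value == 0.0

    def test_k1_rejected(self, micro):
        d, _ = micro
        p = Partition(labels=np.zeros(4, dtype=int), medoids=(0,), K=1)
        for fn in (pc.silhouette_index, pc.ch_index):
            with pytest.raises(ValueError):
                fn(p, d)


class TestMicroOptimality:
    def test_true_2clustering_maximizes_both_indices(self, micro):
        """Brute force over all 7 two-cluster partitions of the micro example."""
        d, _ = micro
        for kind in ("sh", "ch"):
            best_labels, best_val = None, -math.inf
            for labels in two_cluster_partitions(4):
                labels = np.asarray(labels)
                meds = []
                for k in (0, 1):
                    members = np.flatnonzero(labels == k)
                    sums = d.values[np.ix_(members, members)].sum(axis=1)
                    meds.append(int(members[int(np.argmin(sums))]))
                part = Partition(labels=labels, medoids=tuple(meds), K=2)
                val = score_partition(part, d, kind).value
                if val > best_val:
                    best_val, best_labels = val, labels
            assert best_labels.tolist() in ([0, 0, 1, 1],)


class TestSelectK:
    def three_groups(self):
        t1 = pc.parse_newick("((A,B),C,(D,E));")
        t2 = pc.parse_newick("((A,C),B,(D,E));")
        t3 = pc.parse_newick("((A,D),B,(C,E));")
        return pc.pairwise_rf_matrix(pc.TreeSet([t1] * 4 + [t2] * 4 + [t3] * 4))

    @pytest.mark.parametrize("index_kind", ["sh", "ch"])
    def test_recovers_three_separated_groups(self, index_kind):
        rep = pc.select_k(self.three_groups(), index_kind, 2, 6, n_starts=10, seed=1)
        assert rep.best_K == 3

    def test_single_k_report(self):
        rep = pc.select_k(self.three_groups(), "sh", 3, 3, n_starts=5, seed=0)
        assert list(rep.scores) == [3] and rep.best_K == 3

    def test_report_rows_flag_selection(self):
        rep = pc.select_k(self.three_groups(), "sh", 2, 5, n_starts=5, seed=0)
        rows = rep.as_rows()
        assert [r["K"] for r in rows] == [2, 3, 4, 5]
        assert sum(r["selected"] for r in rows) == 1
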