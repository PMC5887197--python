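from itertools import combinations

import numpy as np
import pytest

import phyloclust as pc
from phyloclust.clustering import Partition
from phyloclust.tree_splits import DistanceMatrix

from conftest import two_cluster_partitions


def brute_force_best_2clustering(d):
    """Global optimum of the medoid objective over all 2-cluster partitions."""
    n = d.n
    best = None
    for labels in two_cluster_partitions(n):
        labels = np.asarray(labels)
        meds = []
        for k in (0, 1):
            members = np.flatnonzero(labels == k)
            sums = d.values[np.ix_(members, members)].sum(axis=1)
            meds.append(int(members[int(np.argmin(sums))]))
        obj = pc.objective_med(Partition(labels=labels, medoids=tuple(meds), K=2), d)
        if best is None or obj < best[0]:
            best = (obj, labels)
    return best


class TestObjective:
    def test_singletons_zero(self, micro):
        d, _ = micro
        p = Partition(labels=np.arange(4), medoids=(0, 1, 2, 3), K=4)
        assert pc.objective_med(p, d) == 0

    def test_true_clustering(self, micro):
        d, p = micro
        assert pc.objective_med(p, d) == 4

    def test_crossed_clustering_worse(self, micro):
        d, _ = micro
        p = Partition(labels=np.array([0, 1, 0, 1]), medoids=(0, 1), K=2)
        assert pc.objective_med(p, d) == 16


class TestAssign:
    def test_tie_goes_to_smaller_medoid_index(self):
        v = np.array([[0, 9, 9, 4],
                      [9, 0, 9, 4],
                      [9, 9, 0, 9],
                      [4, 4, 9, 0]], dtype=np.int64)
        d = DistanceMatrix(values=v, kind="rf", n_leaves=8)
        p = pc.assign_to_medoids((1, 0), d)  # order of medoids must not matter
        assert p.labels[3] == np.flatnonzero(np.array(p.medoids) == 0)[0]

    def test_micro_assignment(self, micro):
        d, _ = micro
        p = pc.assign_to_medoids((0, 2), d)
        assert p.labels.tolist() == [0, 0, 1, 1]

    def test_k_equals_n_identity(self, micro):
        d, _ = micro
        p = pc.assign_to_medoids((0, 1, 2, 3), d)
        assert p.labels.tolist() == [0, 1, 2, 3]


class TestUpdateMedoids:
    def test_pair_tie_smallest_index(self, micro):
        d, p = micro
        assert pc.update_medoids(p, d) == (0, 2)

    def test_exhaustive_three_member_cluster(self):
        v = np.array([[0, 2, 2], [2, 0, 4], [2, 4, 0]], dtype=np.int64)
        d = DistanceMatrix(values=v, kind="rf", n_leaves=8)
        p = Partition(labels=np.zeros(3, dtype=int), medoids=(1,), K=1)
        assert pc.update_medoids(p, d) == (0,)  # sums 4, 6, 6


class TestKMedoids:
    def test_micro_recovers_true_clusters(self, micro):
        d, _ = micro
        res = pc.kmedoids(d, 2, n_starts=5, seed=0)
        assert res.objective == 4
        assert sorted(map(sorted, [res.partition.members(k).tolist() for k in range(2)])) \
            == [[0, 1], [2, 3]]

    def test_perfect_groups_objective_zero(self):
        t1 = pc.parse_newick("((A,B),C,(D,E));")
        t2 = pc.parse_newick("((A,C),B,(D,E));")
        ts = pc.TreeSet([t1] * 3 + [t2] * 3)
        d = pc.pairwise_rf_matrix(ts)
        res = pc.kmedoids(d, 2, n_starts=5, seed=1)
        assert res.objective == 0
        assert pc.adjusted_rand_index(res.partition.labels, [0, 0, 0, 1, 1, 1]) == 1

    def test_determinism(self, micro):
        d, _ = micro
        a = pc.kmedoids(d, 2, n_starts=10, seed=123)
        b = pc.kmedoids(d, 2, n_starts=10, seed=123)
        assert np.array_equal(a.partition.labels, b.partition.labels)
        assert a.objective == b.objective and a.partition.medoids == b.partition.medoids

    def test_k_out_of_range(self, micro):
        d, _ = micro
        for K in (1, 4, 7):
            with pytest.raises(ValueError):
                pc.kmedoids(d, K, seed=0)

    def test_objective_monotone_within_start(self):
        rng = np.random.default_rng(17)
        ts = pc.TreeSet([pc.random_binary_tree(10, rng=rng) for _ in range(30)])
        d = pc.pairwise_rf_matrix(ts)
        res = pc.kmedoids(d, 3, n_starts=8, seed=2, keep_all_starts=True)
        for start in res.all_starts:
            h = start.objective_history
            assert all(h[i + 1] <= h[i] for i in range(len(h) - 1))

    def test_voronoi_consistency(self):
        rng = np.random.default_rng(19)
        ts = pc.TreeSet([pc.random_binary_tree(8, rng=rng) for _ in range(25)])
        d = pc.pairwise_rf_matrix(ts)
        res = pc.kmedoids(d, 4, n_starts=5, seed=3)
        part = res.partition
        for i in range(d.n):
            own = d.values[i, part.medoids[part.labels[i]]]
            assert all(own <= d.values[i, m] for m in part.medoids)

    def test_attains_bruteforce_optimum_small_instances(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            ts = pc.TreeSet([pc.random_binary_tree(7, rng=rng) for _ in range(8)])
            d = pc.pairwise_rf_matrix(ts)
            res = pc.kmedoids(d, 2, n_starts=20, seed=int(rng.integers(2 ** 31)))
            assert res.objective == brute_force_best_2clustering(d)[0]


class TestConsensusBaseline:
    def easy_data(self, seed=11):
        cfg = pc.SimulationConfig(n_leaves=16, K=3, trees_per_cluster=10,
                                  noise_level=10, seed=seed)
        return pc.generate_clustered_treeset(cfg)

    def test_pure_groups_objective_zero(self):
        t1 = pc.parse_newick("((A,B),C,(D,E));")
        t2 = pc.parse_newick("((A,C),B,(D,E));")
        ts = pc.TreeSet([t1] * 4 + [t2] * 4)
        res = pc.kmeans_consensus_baseline(ts, 2, n_starts=3, seed=0)
        assert res.objective == 0

    def test_determinism(self):
        data = self.easy_data()
        a = pc.kmeans_consensus_baseline(data.trees, 3, n_starts=3, seed=5)
        b = pc.kmeans_consensus_baseline(data.trees, 3, n_starts=3, seed=5)
        assert np.array_equal(a.partition.labels, b.partition.labels)
        assert a.objective == b.objective

    def test_agrees_with_kmedoids_on_separated_data(self):
        data = self.easy_data()
        base = pc.kmeans_consensus_baseline(data.trees, 3, n_starts=3, seed=5)
        d = pc.pairwise_rf_matrix(data.trees)
        med = pc.kmedoids(d, 3, n_starts=10, seed=5)
        assert pc.adjusted_rand_index(base.partition.labels,
                                      med.partition.labels) == 1
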