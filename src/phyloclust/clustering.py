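"""Partitioning a tree set into K clusters over a precomputed RF matrix.

The core algorithm is k-medoids with Voronoi (alternating) iteration: from a
random set of K distinct medoid trees, assign every tree to its nearest
medoid, recompute each cluster's medoid as the member minimising the total
within-cluster distance, and repeat until the medoid set is stable.  The
objective minimised is

    OF_med = sum_k sum_{i in k} d(medoid_k, tree_i),

with d the (optionally squared) RF distance.  Because the medoid is an
input tree, no consensus tree ever has to be rebuilt during the search -
this is the entire speed advantage over the k-means-style baseline, which
recomputes a majority-rule consensus (the cluster centroid) after every
single relocation and scores

    OF = sum_k sum_{i in k} RF(majority_k, tree_i).

That baseline (the classical characteristic-trees approach) is provided for
comparison as :func:`kmeans_consensus_baseline`.

All ties - nearest medoid, medoid choice, best start - break toward the
smallest tree index, and all randomness flows from one integer seed, so
results are bit-reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .newick_io import TreeSet
from .tree_splits import DistanceMatrix


@dataclass
class Partition:
    """Assignment of N tree indices to K clusters, with medoid indices.

    Cluster ids are 0..K-1 internally; file output is 1-based.
    """

    labels: np.ndarray  # shape (N,), ints in 0..K-1
    medoids: tuple[int, ...]
    K: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.medoids) != self.K:
            raise ValueError("need exactly one medoid per cluster")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.K)):
            raise ValueError("every cluster id in 0..K-1 must be nonempty")
        for k, m in enumerate(self.medoids):
            if self.labels[m] != k:
                raise ValueError(f"medoid {m} of cluster {k} carries label {self.labels[m]}")

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def sizes(self) -> list[int]:
        return [int((self.labels == k).sum()) for k in range(self.K)]


@dataclass
class ClusteringResult:
    partition: Partition
    objective: float
    n_iterations: int
    n_starts: int
    seed: int | None
    converged: bool
    objective_history: list[float] = field(default_factory=list)
    all_starts: list["ClusteringResult"] | None = None


def objective_med(partition: Partition, d: DistanceMatrix) -> float:
    """Total distance from every tree to its cluster's medoid."""
    total = 0.0
    for k, m in enumerate(partition.medoids):
        members = partition.members(k)
        if members.size == 0:
            raise ValueError(f"cluster {k} is empty")
        total += float(d.values[m, members].sum())
    return total


def assign_to_medoids(medoids, d: DistanceMatrix) -> Partition:
    """Nearest-medoid assignment; ties go to the medoid with the smallest tree index."""
    medoids = tuple(int(m) for m in medoids)
    if len(set(medoids)) != len(medoids):
        raise ValueError("medoids must be distinct indices")
    # scan candidate medoids in ascending tree-index order so that argmin's
    # first-wins rule realises the smallest-index tie-break
    order = sorted(range(len(medoids)), key=lambda k: medoids[k])
    sub = d.values[:, [medoids[k] for k in order]]
    pos = np.argmin(sub, axis=1)
    labels = np.asarray(order, dtype=np.int64)[pos]
    # keep each medoid in its own cluster even under 0-distance ties
    lab = labels.copy()
    for k, m in enumerate(medoids):
        lab[m] = k
    if len(np.unique(lab)) != len(medoids):
        raise ValueError("assignment produced an empty cluster (duplicate-topology medoids)")
    return Partition(labels=lab, medoids=medoids, K=len(medoids))


def update_medoids(partition: Partition, d: DistanceMatrix) -> tuple[int, ...]:
    """Per cluster, the member minimising the within-cluster distance sum (ties: smallest index)."""
    out = []
    for k in range(partition.K):
        members = partition.members(k)  # ascending
        sub = d.values[np.ix_(members, members)]
        sums = sub.sum(axis=1)
        out.append(int(members[int(np.argmin(sums))]))  # argmin -> first = smallest index
    return tuple(out)


def _single_start(d: DistanceMatrix, K: int, rng: np.random.Generator,
                  max_iter: int) -> ClusteringResult:
    N = d.n
    # sample distinct medoids, preferring topologically distinct trees
    for _ in range(100):
        meds = tuple(sorted(int(x) for x in rng.choice(N, size=K, replace=False)))
        offdiag = d.values[np.ix_(meds, meds)][~np.eye(K, dtype=bool)]
        if np.all(offdiag > 0):
            break
    part = assign_to_medoids(meds, d)
    history = [objective_med(part, d)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_meds = update_medoids(part, d)
        new_meds = tuple(sorted(new_meds))
        if new_meds == tuple(sorted(part.medoids)):
            converged = True
            break
        part = assign_to_medoids(new_meds, d)
        history.append(objective_med(part, d))
    return ClusteringResult(partition=part, objective=history[-1], n_iterations=it,
                            n_starts=1, seed=None, converged=converged,
                            objective_history=history)


def kmedoids(d: DistanceMatrix, K: int, n_starts: int = 30, max_iter: int = 100,
             seed: int | None = None, keep_all_starts: bool = False) -> ClusteringResult:
    """Best-of-starts k-medoids over a precomputed distance matrix.

    Each start draws K distinct random medoids, then alternates nearest-medoid
    assignment and medoid update until the medoid set stabilises.  The
    returned result has the minimum objective over starts (ties: earliest
    start).  Deterministic given ``seed``.

    ``keep_all_starts`` retains every start's result, which benchmark code
    uses to re-select the best start by a cluster validity index instead of
    by the objective.
    """
    N = d.n
    if not (2 <= K <= N - 1):
        raise ValueError(f"K={K} out of range [2, {N - 1}]")
    rng = np.random.default_rng(seed)
    starts = [_single_start(d, K, rng, max_iter) for _ in range(n_starts)]
    best = min(range(n_starts), key=lambda s: (starts[s].objective, s))
    res = starts[best]
    return ClusteringResult(partition=res.partition, objective=res.objective,
                            n_iterations=res.n_iterations, n_starts=n_starts,
                            seed=seed, converged=res.converged,
                            objective_history=res.objective_history,
                            all_starts=starts if keep_all_starts else None)


# ---------------------------------------------------------------------------
# k-means / consensus-recomputation baseline


def _majority_masks(counts: Counter, n_k: int) -> list[int]:
    half = n_k / 2.0
    return [m for m, c in counts.items() if c > half]


def _cluster_cost(maj: list[int], member_masks: list[frozenset]) -> float:
    maj_set = frozenset(maj)
    return float(sum(len(maj_set ^ sm) for sm in member_masks))


def _cluster_cost_sq(maj: list[int], member_masks: list[frozenset]) -> float:
    maj_set = frozenset(maj)
    return float(sum(len(maj_set ^ sm) ** 2 for sm in member_masks))


def kmeans_consensus_baseline(trees: TreeSet, K: int, n_starts: int = 5,
                              max_iter: int = 100, seed: int | None = None,
                              squared: bool = True) -> ClusteringResult:
    """k-means-style tree clustering with majority-consensus centroids.

    The cluster centre is the majority-rule consensus tree, recomputed after
    each basic operation (relocating one tree between clusters); the
    objective is ``sum_k sum_i RF(majority_k, tree_i)``, squared per term
    when ``squared`` (the classical characteristic-trees variant).  A
    relocation that would empty its source cluster is rejected.

    Deliberately faithful to the expensive formulation: it exists as the
    running-time and accuracy comparator for :func:`kmedoids`.
    """
    N = len(trees)
    if not (2 <= K <= N - 1):
        raise ValueError(f"K={K} out of range [2, {N - 1}]")
    rng = np.random.default_rng(seed)
    masks = [t.split_masks for t in trees]
    cost = _cluster_cost_sq if squared else _cluster_cost

    def total_objective(labels: np.ndarray) -> float:
        tot = 0.0
        for k in range(K):
            members = np.flatnonzero(labels == k)
            counts: Counter = Counter()
            for i in members:
                counts.update(masks[i])
            tot += cost(_majority_masks(counts, members.size), [masks[i] for i in members])
        return tot

    best_res: ClusteringResult | None = None
    for start in range(n_starts):
        # seed clusters from K random distinct trees via nearest-neighbour
        # assignment (same start style as k-medoids, so the comparison is
        # about the iteration cost, not the initialisation)
        for _ in range(100):
            seeds = sorted(int(x) for x in rng.choice(N, size=K, replace=False))
            if all(masks[a] != masks[b] for i, a in enumerate(seeds) for b in seeds[i + 1:]):
                break
        labels = np.empty(N, dtype=np.int64)
        for i in range(N):
            labels[i] = min(range(K), key=lambda k: (len(masks[i] ^ masks[seeds[k]]), seeds[k]))
        for k, s in enumerate(seeds):
            labels[s] = k
        counts = [Counter() for _ in range(K)]
        for i in range(N):
            counts[labels[i]].update(masks[i])
        sizes = [int((labels == k).sum()) for k in range(K)]
        cluster_obj = [cost(_majority_masks(counts[k], sizes[k]),
                            [masks[i] for i in np.flatnonzero(labels == k)])
                       for k in range(K)]
        history = [float(sum(cluster_obj))]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            moved = False
            for i in range(N):
                k = int(labels[i])
                if sizes[k] == 1:
                    continue  # relocation would empty the cluster: rejected
                # cost of source cluster without i
                counts[k].subtract(masks[i])
                src_members = [j for j in np.flatnonzero(labels == k) if j != i]
                src_new = cost(_majority_masks(counts[k], sizes[k] - 1),
                               [masks[j] for j in src_members])
                best_delta = 0.0
                best_k2 = -1
                best_dst_new = 0.0
                for k2 in range(K):
                    if k2 == k:
                        continue
                    counts[k2].update(masks[i])
                    dst_members = list(np.flatnonzero(labels == k2)) + [i]
                    dst_new = cost(_majority_masks(counts[k2], sizes[k2] + 1),
                                   [masks[j] for j in dst_members])
                    counts[k2].subtract(masks[i])
                    delta = (src_new + dst_new) - (cluster_obj[k] + cluster_obj[k2])
                    if delta < best_delta - 1e-9:
                        best_delta = delta
                        best_k2 = k2
                        best_dst_new = dst_new
                if best_k2 >= 0:
                    labels[i] = best_k2
                    counts[best_k2].update(masks[i])
                    sizes[k] -= 1
                    sizes[best_k2] += 1
                    cluster_obj[k] = src_new
                    cluster_obj[best_k2] = best_dst_new
                    moved = True
                else:
                    counts[k].update(masks[i])  # restore
            history.append(float(sum(cluster_obj)))
            if not moved:
                converged = True
                break
        # medoid-style representatives for reporting: member closest to the
        # majority consensus of its cluster (ties: smallest index)
        meds = []
        for k in range(K):
            members = np.flatnonzero(labels == k)
            maj = frozenset(_majority_masks(counts[k], sizes[k]))
            meds.append(int(min(members, key=lambda j: (len(maj ^ masks[j]), j))))
        part = Partition(labels=labels.copy(), medoids=tuple(meds), K=K)
        res = ClusteringResult(partition=part, objective=history[-1], n_iterations=it,
                               n_starts=n_starts, seed=seed, converged=converged,
                               objective_history=history)
        if best_res is None or res.objective < best_res.objective:
            best_res = res
    assert best_res is not None
    return best_res
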