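"""Tree-adapted Silhouette and Calinski-Harabasz indices; choosing K.

Both indices are rewritten for a set of trees known only through the matrix
of pairwise RF (or squared-RF) distances.

Silhouette.  For tree i in cluster k,

    a(i) = sum_{j in k} d(i, j) / N_k
    b(i) = min over foreign clusters k' of  sum_{j in k'} d(i, j) / N_k'
    s(i) = (b(i) - a(i)) / max(a(i), b(i))        (0 when the max is 0)

Note the a(i) denominator is N_k with the zero self-term included in the
sum, not the classical N_k - 1: a singleton cluster therefore scores
s(i) = 1, which lets a lone outlying gene tree form its own cluster.
Per-cluster scores sh(k) are the mean s(i) over the cluster, and SH(K) is
the *unweighted* mean of the K cluster scores.

Calinski-Harabasz.  The Euclidean dispersions are replaced by distances to
medoid trees:

    SS_W = sum_k sum_{i in k} d(medoid_k, i)      (= the k-medoids objective)
    SS_B = sum_k N_k * d(medoid_k, global_medoid)
    CH   = (SS_B / SS_W) * (N - K) / (K - 1)

where the global medoid is the tree minimising the total distance to all N
trees.  Perfect separation (SS_W = 0, SS_B > 0) scores +inf; SS_B = 0
scores 0.

The optimal K maximises the chosen index.  Neither index is defined for
K = 1 (a homogeneous set cannot be diagnosed this way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusteringResult, Partition, kmedoids, objective_med
from .tree_splits import DistanceMatrix


@dataclass
class ValidityScore:
    index_kind: str  # "sh" | "ch"
    K: int
    value: float
    per_cluster: list[float] | tuple[float, float]  # sh(k) list, or (SS_W, SS_B)


@dataclass
class KSelectionReport:
    scores: dict[int, ValidityScore]
    best_K: int
    best_partition: Partition
    results: dict[int, ClusteringResult] = field(default_factory=dict)
    index_kind: str = "sh"

    def as_rows(self):
        """Per-K rows (K, objective, score, medoids) for tabular reports."""
        rows = []
        for K in sorted(self.scores):
            res = self.results.get(K)
            rows.append({
                "K": K,
                "objective": res.objective if res else math.nan,
                self.index_kind: self.scores[K].value,
                "medoids": list(res.partition.medoids) if res else [],
                "selected": K == self.best_K,
            })
        return rows


def _check_k_range(K: int, N: int) -> None:
    if K < 2:
        raise ValueError("validity indices are undefined for K = 1")
    if K > N - 1:
        raise ValueError(f"K={K} exceeds N-1={N - 1}")


def a_value(i: int, partition: Partition, d: DistanceMatrix) -> float:
    """Mean distance from tree i to its own cluster, self-term included in N_k."""
    members = partition.members(int(partition.labels[i]))
    return float(d.values[i, members].sum()) / members.size


def b_value(i: int, partition: Partition, d: DistanceMatrix) -> float:
    """Smallest mean distance from tree i to any foreign cluster."""
    if partition.K < 2:
        raise ValueError("b(i) needs at least two clusters")
    own = int(partition.labels[i])
    best = math.inf
    for k in range(partition.K):
        if k == own:
            continue
        members = partition.members(k)
        best = min(best, float(d.values[i, members].sum()) / members.size)
    return best


def _cluster_mean_matrix(partition: Partition, d: DistanceMatrix) -> np.ndarray:
    """M[i, k] = mean distance from tree i to the members of cluster k."""
    cols = []
    for k in range(partition.K):
        members = partition.members(k)
        cols.append(d.values[:, members].sum(axis=1) / members.size)
    return np.column_stack(cols)


def silhouette_index(partition: Partition, d: DistanceMatrix) -> ValidityScore:
    """SH(K): unweighted mean over clusters of the mean element silhouette."""
    _check_k_range(partition.K, d.n)
    M = _cluster_mean_matrix(partition, d)
    idx = np.arange(d.n)
    a = M[idx, partition.labels]
    Mf = M.copy()
    Mf[idx, partition.labels] = np.inf
    b = Mf.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    sh_k = [float(s[partition.members(k)].mean()) for k in range(partition.K)]
    return ValidityScore(index_kind="sh", K=partition.K,
                         value=float(np.mean(sh_k)), per_cluster=sh_k)


def ss_w(partition: Partition, d: DistanceMatrix) -> float:
    """Within-cluster dispersion: total distance to cluster medoids (= OF_med)."""
    return objective_med(partition, d)


def global_medoid(d: DistanceMatrix) -> int:
    """Tree minimising the total distance to all trees (ties: smallest index)."""
    return int(np.argmin(d.values.sum(axis=1)))


def ss_b(partition: Partition, d: DistanceMatrix) -> float:
    """Between-cluster dispersion: size-weighted medoid-to-global-medoid distances."""
    g = global_medoid(d)
    total = 0.0
    for k, m in enumerate(partition.medoids):
        total += partition.members(k).size * float(d.values[m, g])
    return total


def ch_index(partition: Partition, d: DistanceMatrix) -> ValidityScore:
    """CH = (SS_B / SS_W) * (N - K) / (K - 1), with medoid-tree dispersions."""
    _check_k_range(partition.K, d.n)
    w = ss_w(partition, d)
    b = ss_b(partition, d)
    if w == 0.0:
        value = math.inf if b > 0 else 0.0
    elif b == 0.0:
        value = 0.0
    else:
        value = (b / w) * (d.n - partition.K) / (partition.K - 1)
    return ValidityScore(index_kind="ch", K=partition.K, value=float(value),
                         per_cluster=(w, b))


def score_partition(partition: Partition, d: DistanceMatrix, index_kind: str) -> ValidityScore:
    if index_kind == "sh":
        return silhouette_index(partition, d)
    if index_kind == "ch":
        return ch_index(partition, d)
    raise ValueError(f"unknown index {index_kind!r}; expected 'sh' or 'ch'")


def best_start_by_index(d: DistanceMatrix, K: int, index_kind: str,
                        n_starts: int = 30, max_iter: int = 100,
                        seed: int | None = None) -> tuple[ClusteringResult, ValidityScore]:
    """k-medoids at fixed K, keeping the start that maximises the validity index.

    The index is the arbiter among random starts (its first role, before it
    compares different K); ties break by lower objective, then earlier start.
    """
    res = kmedoids(d, K, n_starts=n_starts, max_iter=max_iter, seed=seed,
                   keep_all_starts=True)
    best = None
    best_score = None
    best_key = None
    for s, r in enumerate(res.all_starts):
        score = score_partition(r.partition, d, index_kind)
        key = (-score.value, r.objective, s)
        if best_key is None or key < best_key:
            best_key, best, best_score = key, r, score
    best = ClusteringResult(partition=best.partition, objective=best.objective,
                            n_iterations=best.n_iterations, n_starts=n_starts,
                            seed=seed, converged=best.converged,
                            objective_history=best.objective_history)
    return best, best_score


def select_k(d: DistanceMatrix, index_kind: str = "sh", k_min: int = 2,
             k_max: int = 10, n_starts: int = 30, max_iter: int = 100,
             seed: int | None = None) -> KSelectionReport:
    """Run k-medoids for each K in [k_min, k_max] and pick the index argmax.

    The validity index plays both of its roles: at each fixed K it selects
    the best partition over the random starts, and across K the argmax of
    the index (ties: smallest K) gives best_K.  All per-K scores are
    retained for reporting/plotting.
    """
    N = d.n
    _check_k_range(k_min, N)
    k_max = min(k_max, N - 1)
    if k_min > k_max:
        raise ValueError(f"empty K range [{k_min}, {k_max}]")
    ss = np.random.SeedSequence(seed)
    scores: dict[int, ValidityScore] = {}
    results: dict[int, ClusteringResult] = {}
    for K, child in zip(range(k_min, k_max + 1), ss.spawn(k_max - k_min + 1)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        res, score = best_start_by_index(d, K, index_kind, n_starts=n_starts,
                                         max_iter=max_iter, seed=sub_seed)
        results[K] = res
        scores[K] = score
    best_K = max(sorted(scores), key=lambda K: (scores[K].value, -K))
    return KSelectionReport(scores=scores, best_K=best_K,
                            best_partition=results[best_K].partition,
                            results=results, index_kind=index_kind)
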