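"""Seeded generator of clustered gene-tree sets, plus the two benchmark protocols.

The generator emulates the structure of gene-tree collections produced by
hybridisation/coalescent simulators: K cluster-centre topologies that
differ from the first centre by a small number of large rearrangements
(SPR moves, the topological footprint of hybridisation or horizontal gene
transfer), each surrounded by a cloud of noisy trees obtained by repeated
small rearrangements (NNI moves, the analogue of incomplete lineage
sorting).  The two scales - inter-cluster divergence versus intra-cluster
noise - are the only features downstream clustering relies on.

The noise knob follows a 1..10 convention (10 = low noise, 1 = high
noise).  Each cluster member receives m independent NNI moves with

    m = max(1, round((n_leaves - 3) * (11 - noise_level) / 10))   for level <= 9,

and at level 10 a member is either unperturbed (probability 1/2) or one NNI
away from its centre.  The mapping is a convention; what matters is that it
is monotone (lower level, more noise) and seeded.

All randomness flows from a single integer seed via numpy Generators, and
identical configurations produce byte-identical Newick output.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ari import adjusted_rand_index
from .clustering import kmeans_consensus_baseline
from .newick_io import LabeledTree, TreeSet
from .tree_splits import pairwise_rf_matrix
from .validity import best_start_by_index


@dataclass
class SimulationConfig:
    """Conditions for one clustered tree set.

    divergence_moves is the inclusive range of SPR moves separating each
    non-first centre from centre 1 (the hybridisation-rate analogue);
    noise_level in 1..10 is the coalescence-rate analogue described above.
    """

    n_leaves: int = 16
    K: int = 5
    trees_per_cluster: int = 100
    divergence_moves: tuple[int, int] = (1, 4)
    noise_level: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.trees_per_cluster < 1:
            raise ValueError("trees_per_cluster must be >= 1")
        lo, hi = self.divergence_moves
        if not (1 <= lo <= hi):
            raise ValueError("divergence_moves must be a range with 1 <= lo <= hi")
        if not (1 <= self.noise_level <= 10):
            raise ValueError("noise_level must be in 1..10")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["divergence_moves"] = list(self.divergence_moves)
        return json.dumps(d, indent=2)


@dataclass
class LabeledTreeSet:
    trees: TreeSet
    true_labels: np.ndarray  # cluster id per tree, 0-based
    centers: list[LabeledTree] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mutable adjacency representation used only inside the generator


class _Graph:
    """Unrooted tree as an adjacency map; leaves are nodes 0..n-1."""

    def __init__(self, n_leaves: int):
        self.adj: dict[int, set[int]] = {}
        self.n_leaves = n_leaves
        self._next = n_leaves

    def new_node(self) -> int:
        v = self._next
        self._next += 1
        self.adj[v] = set()
        return v

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def edges(self) -> list[tuple[int, int]]:
        return sorted((u, v) for u in self.adj for v in self.adj[u] if u < v)

    def suppress_degree2(self, v: int) -> None:
        if len(self.adj[v]) == 2:
            a, b = sorted(self.adj[v])
            self.remove_edge(v, a)
            self.remove_edge(v, b)
            del self.adj[v]
            self.add_edge(a, b)

    def copy(self) -> "_Graph":
        g = _Graph(self.n_leaves)
        g.adj = {u: set(vs) for u, vs in self.adj.items()}
        g._next = self._next
        return g

    def to_tree(self, labels: list[str]) -> LabeledTree:
        n = self.n_leaves
        order = sorted(range(n), key=lambda i: labels[i])
        bit = {leaf: 1 << pos for pos, leaf in enumerate(order)}
        full = (1 << n) - 1
        masks: set[int] = set()
        root = next(iter(self.adj))
        # iterative DFS computing the leaf mask under each edge
        seen_mask: dict[tuple[int, int], int] = {}

        def subtree_mask(parent: int, node: int) -> int:
            stack = [(parent, node, False)]
            while stack:
                p, u, done = stack.pop()
                if done:
                    m = bit.get(u, 0) if u < n else 0
                    for w in self.adj[u]:
                        if w != p:
                            m |= seen_mask[(u, w)]
                    seen_mask[(p, u)] = m
                else:
                    stack.append((p, u, True))
                    for w in self.adj[u]:
                        if w != p:
                            stack.append((u, w, False))
            return seen_mask[(parent, node)]

        for u, v in self.edges():
            m = subtree_mask(u, v)
            side = (full & ~m) if (m & 1) else m
            if 2 <= side.bit_count() <= n - 2:
                masks.add(side)
        return LabeledTree(sorted(labels), masks)


def _graph_from_tree(tree: LabeledTree) -> tuple[_Graph, list[str]]:
    """Rebuild an adjacency graph from a tree's laminar split family."""
    n = tree.n_leaves
    labels = list(tree.labels)
    g = _Graph(n)
    sides = sorted(tree.split_masks, key=lambda m: -m.bit_count())
    parent: dict[int, int | None] = {}
    placed: list[int] = []
    for m in sides:
        par = None
        for cand in reversed(placed):
            if m & cand == m:
                par = cand
                break
        parent[m] = par
        placed.append(m)
    node_of: dict[int, int] = {}
    root = g.new_node()
    for m in sides:
        node_of[m] = g.new_node()
    for m in sides:
        p = parent[m]
        g.add_edge(node_of[m], root if p is None else node_of[p])
    # attach each leaf to the node of the smallest side containing it (or root)
    by_size = sorted(sides, key=lambda m: m.bit_count())
    for i in range(n):
        b = 1 << i
        host = root
        for m in by_size:
            if m & b:
                host = node_of[m]
                break
        g.add_edge(i, host)
    return g, labels


def _default_labels(n: int) -> list[str]:
    return [f"L{i + 1}" for i in range(n)]


def random_binary_tree(n_leaves: int, seed: int | None = None,
                       rng: np.random.Generator | None = None) -> LabeledTree:
    """Uniform-attachment random unrooted binary tree with labels L1..Ln."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = _default_labels(n_leaves)
    g = _Graph(n_leaves)
    hub = g.new_node()
    for i in range(3):
        g.add_edge(i, hub)
    for i in range(3, n_leaves):
        edges = g.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        g.remove_edge(u, v)
        w = g.new_node()
        g.add_edge(u, w)
        g.add_edge(v, w)
        g.add_edge(i, w)
    return g.to_tree(labels)


def _is_binary(tree: LabeledTree) -> bool:
    return len(tree.split_masks) == tree.n_leaves - 3


def _reachable(g: _Graph, start: int, target: int) -> bool:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        if u == target:
            return True
        for w in g.adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _spr_on_graph(g: _Graph, rng: np.random.Generator) -> None:
    """One random SPR applied in place to a binary tree graph."""
    for _ in range(200):
        edges = g.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        if rng.integers(2):
            u, v = v, u
        if len(g.adj[v]) < 3:
            continue  # attachment node must be internal
        g.remove_edge(u, v)
        a, b = sorted(g.adj[v])
        g.suppress_degree2(v)
        ab = tuple(sorted((a, b)))
        # regraft edges: the remaining component, minus the edge the prune closed
        remaining = [e for e in g.edges() if e != ab and _reachable(g, e[0], a)]
        if not remaining:  # undo and retry with another prune edge
            g.remove_edge(a, b)
            w = g.new_node()
            g.add_edge(a, w)
            g.add_edge(b, w)
            g.add_edge(u, w)
            continue
        x, y = remaining[int(rng.integers(len(remaining)))]
        w = g.new_node()
        g.remove_edge(x, y)
        g.add_edge(x, w)
        g.add_edge(y, w)
        g.add_edge(u, w)
        return
    raise RuntimeError("no legal SPR move found")


def _nni_on_graph(g: _Graph, rng: np.random.Generator) -> None:
    """One random NNI applied in place; changes exactly one split."""
    internal = [(u, v) for u, v in g.edges()
                if len(g.adj[u]) >= 3 and len(g.adj[v]) >= 3]
    if not internal:
        raise ValueError("tree has no internal edge")
    u, v = internal[int(rng.integers(len(internal)))]
    nu = sorted(w for w in g.adj[u] if w != v)
    nv = sorted(w for w in g.adj[v] if w != u)
    a = nu[int(rng.integers(len(nu)))]
    c = nv[int(rng.integers(len(nv)))]
    g.remove_edge(u, a)
    g.remove_edge(v, c)
    g.add_edge(v, a)
    g.add_edge(u, c)


def spr_move(tree: LabeledTree, seed: int | None = None,
             rng: np.random.Generator | None = None) -> LabeledTree:
    """One random subtree-prune-and-regraft on a binary tree.

    The pruned edge and the regraft edge are drawn uniformly among legal
    choices; regrafting onto the edge closed by the prune is excluded, and
    draws are repeated if the move happens to restore the input topology,
    so the output differs whenever a topology-changing move exists.
    """
    if not _is_binary(tree) or tree.n_leaves < 4:
        raise ValueError("SPR move requires a binary tree with >= 4 leaves")
    rng = rng if rng is not None else np.random.default_rng(seed)
    for _ in range(200):
        g, labels = _graph_from_tree(tree)
        _spr_on_graph(g, rng)
        out = g.to_tree(labels)
        if out != tree:
            return out
    raise RuntimeError("no topology-changing SPR move found")


def nni_move(tree: LabeledTree, seed: int | None = None,
             rng: np.random.Generator | None = None) -> LabeledTree:
    """One random nearest-neighbour interchange; RF(input, output) = 2."""
    if not _is_binary(tree) or tree.n_leaves < 4:
        raise ValueError("NNI move requires a binary tree with >= 4 leaves")
    rng = rng if rng is not None else np.random.default_rng(seed)
    g, labels = _graph_from_tree(tree)
    _nni_on_graph(g, rng)
    return g.to_tree(labels)


def _noise_moves(n_leaves: int, noise_level: int, rng: np.random.Generator) -> int:
    if noise_level >= 10:
        return 0 if rng.integers(2) else 1
    return max(1, round((n_leaves - 3) * (11 - noise_level) / 10))


def generate_clustered_treeset(config: SimulationConfig) -> LabeledTreeSet:
    """K centre topologies plus a cloud of NNI-perturbed members per centre.

    Centre 1 is a uniform-attachment random binary tree; each further centre
    is centre 1 transformed by h SPR moves, h drawn uniformly from the
    divergence range, resampled until all centres are pairwise distinct.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.divergence_moves
    centers = [random_binary_tree(config.n_leaves, rng=rng)]
    g1, leaf_labels = _graph_from_tree(centers[0])
    for _ in range(config.K - 1):
        for attempt in range(1000):
            h = int(rng.integers(lo, hi + 1))
            g = g1.copy()
            for _ in range(h):
                _spr_on_graph(g, rng)
            cand = g.to_tree(leaf_labels)
            if all(cand != c for c in centers):
                centers.append(cand)
                break
        else:
            raise RuntimeError(
                "could not generate pairwise-distinct cluster centres; "
                "use a larger n_leaves or a wider divergence range")
    trees: list[LabeledTree] = []
    labels: list[int] = []
    for k, center in enumerate(centers):
        gc, _ = _graph_from_tree(center)
        for _ in range(config.trees_per_cluster):
            m = _noise_moves(config.n_leaves, config.noise_level, rng)
            if m == 0:
                trees.append(center)
            else:
                g = gc.copy()
                for _ in range(m):
                    _nni_on_graph(g, rng)
                trees.append(g.to_tree(leaf_labels))
            labels.append(k)
    return LabeledTreeSet(trees=TreeSet(trees), true_labels=np.asarray(labels),
                          centers=centers)


# ---------------------------------------------------------------------------
# benchmark protocols


_VARIANTS = [("sh", False), ("ch", False), ("sh", True), ("ch", True)]


def _best_start_by_index(d, K, index_kind, n_starts, max_iter, seed):
    # with K known, selecting the best start is the only role the validity
    # index plays; it is what distinguishes the SH- and CH-based variants
    res, _ = best_start_by_index(d, K, index_kind, n_starts=n_starts,
                                 max_iter=max_iter, seed=seed)
    return res


def run_protocol_1(k_values=range(2, 11), n_values=(8, 16, 32, 64),
                   noise_values=(5,), trees_per_cluster: int = 100,
                   replicates: int = 10, n_starts: int = 10,
                   max_iter: int = 100, seed: int | None = None) -> pd.DataFrame:
    """Known-K benchmark of the four method variants (SH/CH x RF/RF^2).

    For every (K, n, noise, replicate) cell a clustered tree set is
    generated, k-medoids is run at the true K on the plain and squared RF
    matrices, the best start is chosen by each validity index, and the ARI
    against the true labels is recorded.  Returns a tidy DataFrame with one
    row per cell and variant.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for K in k_values:
        for n in n_values:
            for noise in noise_values:
                for rep in range(replicates):
                    child = ss.spawn(1)[0]
                    gseed = int(child.generate_state(1)[0] % (2 ** 31))
                    cfg = SimulationConfig(n_leaves=n, K=K,
                                           trees_per_cluster=trees_per_cluster,
                                           noise_level=noise, seed=gseed)
                    data = generate_clustered_treeset(cfg)
                    d_plain = pairwise_rf_matrix(data.trees, squared=False)
                    mats = {False: d_plain,
                            True: pairwise_rf_matrix(data.trees, squared=True)}
                    for index_kind, squared in _VARIANTS:
                        res = _best_start_by_index(mats[squared], K, index_kind,
                                                   n_starts, max_iter, gseed + 1)
                        ari = adjusted_rand_index(data.true_labels,
                                                  res.partition.labels)
                        rows.append({"K": K, "n_leaves": n, "noise": noise,
                                     "replicate": rep, "index": index_kind,
                                     "squared": squared, "ari": ari})
    return pd.DataFrame(rows)


def run_protocol_2(n_values=(8, 16, 32, 64, 128), K: int = 5, noise: int = 5,
                   trees_per_cluster: int = 100, replicates: int = 10,
                   n_starts: int = 5, max_iter: int = 100,
                   seed: int | None = None) -> pd.DataFrame:
    """Head-to-head of k-medoids+SH+RF against the consensus-recomputation baseline.

    Per cell, both methods cluster the same generated tree set at the true
    K; ARI and wall-clock seconds are recorded.  The k-medoids timing
    includes the RF-matrix precomputation (it is part of the method)."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for n in n_values:
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            gseed = int(child.generate_state(1)[0] % (2 ** 31))
            cfg = SimulationConfig(n_leaves=n, K=K,
                                   trees_per_cluster=trees_per_cluster,
                                   noise_level=noise, seed=gseed)
            data = generate_clustered_treeset(cfg)

            t0 = time.perf_counter()
            d = pairwise_rf_matrix(data.trees, squared=False)
            res_a = _best_start_by_index(d, K, "sh", n_starts, max_iter, gseed + 1)
            t_a = time.perf_counter() - t0
            ari_a = adjusted_rand_index(data.true_labels, res_a.partition.labels)

            t0 = time.perf_counter()
            res_b = kmeans_consensus_baseline(data.trees, K, n_starts=n_starts,
                                              max_iter=max_iter, seed=gseed + 1,
                                              squared=True)
            t_b = time.perf_counter() - t0
            ari_b = adjusted_rand_index(data.true_labels, res_b.partition.labels)

            rows.append({"n_leaves": n, "replicate": rep, "method": "kmedoids_sh_rf",
                         "ari": ari_a, "seconds": t_a})
            rows.append({"n_leaves": n, "replicate": rep, "method": "kmeans_consensus_rf2",
                         "ari": ari_b, "seconds": t_b})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exhaustive topology enumeration (small n), used by oracle-style checks


def enumerate_binary_topologies(n_leaves: int) -> list[LabeledTree]:
    """All (2n-5)!! unrooted binary topologies on labels L1..Ln (n <= 7 sensible)."""
    labels = _default_labels(n_leaves)
    base = _Graph(n_leaves)  # leaf ids 0..n-1 reserved; internal ids from n
    hub = base.new_node()
    for i in range(3):
        base.add_edge(i, hub)
    graphs = [base]
    for i in range(3, n_leaves):
        nxt = []
        for g in graphs:
            for (u, v) in g.edges():
                h = g.copy()
                h.remove_edge(u, v)
                w = h.new_node()
                h.add_edge(u, w)
                h.add_edge(v, w)
                h.add_edge(i, w)
                nxt.append(h)
        graphs = nxt
    return [g.to_tree(labels) for g in graphs]


def enumerate_all_topologies(n_leaves: int) -> list[LabeledTree]:
    """All unrooted topologies on L1..Ln, multifurcations included.

    Enumerates every pairwise-compatible family of nontrivial canonical
    splits; feasible only for small n (26 topologies at n = 5).
    """
    labels = _default_labels(n_leaves)
    n = n_leaves
    sides = [m for m in range(1 << n)
             if not (m & 1) and 2 <= m.bit_count() <= n - 2]
    from .consensus import _masks_compatible
    trees: list[LabeledTree] = []

    def extend(chosen: tuple[int, ...], start: int):
        trees.append(LabeledTree(labels, chosen))
        for idx in range(start, len(sides)):
            m = sides[idx]
            if all(_masks_compatible(m, c) for c in chosen):
                extend(chosen + (m,), idx + 1)

    extend((), 0)
    return trees
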