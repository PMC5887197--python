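"""Bipartitions and the Robinson-Foulds topological distance.

The RF distance between two trees on the same leaf set is the size of the
symmetric difference of their nontrivial split sets.  It counts *both*
directions of disagreement, so for two fully resolved (binary) trees on n
leaves the maximum is 2(n-3) = 2n-6 and the value is always even.  Branch
lengths play no role.

All downstream clustering work consumes an N x N matrix of pairwise RF (or
squared RF) values computed once here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .newick_io import LabeledTree, TreeSet


@dataclass(frozen=True)
class DistanceMatrix:
    """Precomputed pairwise tree distances.

    ``kind`` records whether entries are plain RF counts or their squares;
    the choice propagates unchanged into every objective and validity-index
    formula, realising the squared/unsquared method variants.
    """

    values: np.ndarray
    kind: str  # "rf" | "rf_squared"
    n_leaves: int

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.kind not in ("rf", "rf_squared"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_phylip(self, path) -> None:
        """Export as a tab-separated square matrix with tree indices as row labels."""
        n = self.n
        lines = [str(n)]
        for i in range(n):
            row = "\t".join(str(int(x)) if float(x).is_integer() else repr(float(x))
                            for x in self.values[i])
            lines.append(f"t{i}\t{row}")
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)


def splits_of_tree(tree: LabeledTree) -> frozenset[frozenset[str]]:
    """Canonical nontrivial splits of a tree, one per internal edge.

    A binary tree on n leaves yields exactly n-3 splits; a star tree yields
    the empty set.  Each split is reported as the side not containing the
    reference leaf (the smallest label).
    """
    if tree.n_leaves < 3:
        raise ValueError("splits are defined for trees with at least 3 leaves")
    return tree.splits()


def _check_same_leaves(a: LabeledTree, b: LabeledTree) -> None:
    if a.labels != b.labels:
        diff = sorted(a.leaf_set ^ b.leaf_set)
        raise ValueError(f"trees are on different leaf sets (difference: {', '.join(diff)})")


def rf_distance(a: LabeledTree, b: LabeledTree) -> int:
    """Robinson-Foulds distance: |splits(a) symmetric-difference splits(b)|."""
    _check_same_leaves(a, b)
    return len(a.split_masks ^ b.split_masks)


def normalized_rf(a: LabeledTree, b: LabeledTree) -> float:
    """RF distance scaled by its maximum 2n-6 over binary trees; in [0, 1]."""
    _check_same_leaves(a, b)
    n = a.n_leaves
    if n <= 3:
        raise ValueError("normalized RF needs n >= 4 (2n-6 must be positive)")
    return rf_distance(a, b) / (2 * n - 6)


def pairwise_rf_matrix(trees: TreeSet, squared: bool = False) -> DistanceMatrix:
    """All pairwise RF distances of a tree set, optionally squared.

    Computed once and reused by clustering and validity indices; O(N^2)
    split-set comparisons with hashed canonical splits.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees for a distance matrix")
    n = len(trees)
    masks = [t.split_masks for t in trees]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        mi = masks[i]
        for j in range(i + 1, n):
            v = len(mi ^ masks[j])
            d[i, j] = d[j, i] = v
    if squared:
        d = d * d
    return DistanceMatrix(values=d, kind="rf_squared" if squared else "rf",
                          n_leaves=trees.n_leaves)
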