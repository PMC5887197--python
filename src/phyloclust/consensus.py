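"""Strict, majority-rule and extended-majority consensus trees.

A consensus tree summarises a profile of trees on one leaf set by keeping
splits according to how often they occur:

* strict      - splits present in every input tree;
* majority    - splits present in strictly more than half of the inputs
                (such splits are automatically pairwise compatible);
* extended    - the majority splits, plus residual splits added greedily in
  (greedy)      decreasing frequency, each accepted only if compatible with
                everything accepted so far.

The majority tree is also a median of the profile under the RF distance,
which is what makes it (and its medoid approximation) a sensible cluster
centre for tree clustering.

Ties among equal-frequency residual splits are broken by the sorted label
tuple of the canonical side, ascending, so that runs are reproducible; the
classical greedy rule leaves this choice arbitrary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .newick_io import LabeledTree, TreeSet


@dataclass
class SplitFrequencyTable:
    """Occurrence count of every nontrivial split across a tree profile."""

    counts: Counter  # canonical split mask -> count
    n_trees: int
    labels: tuple[str, ...]

    def items(self):
        return self.counts.items()


def split_frequencies(trees: TreeSet) -> SplitFrequencyTable:
    """Exact multiset count of every nontrivial split across the input."""
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.split_masks)
    return SplitFrequencyTable(counts=counts, n_trees=len(trees),
                               labels=trees.trees[0].labels)


def is_compatible(s: Iterable[str], t: Iterable[str], leaf_set: Iterable[str]) -> bool:
    """Can two splits co-occur in one tree?

    For sides A|B and C|D this holds iff at least one of the four
    intersections A&C, A&D, B&C, B&D is empty.
    """
    leaves = frozenset(leaf_set)
    a = frozenset(s)
    c = frozenset(t)
    b = leaves - a
    d = leaves - c
    return not (a & c) or not (a & d) or not (b & c) or not (b & d)


def _masks_compatible(a: int, b: int) -> bool:
    # canonical sides exclude the reference leaf, so their complements always
    # intersect; compatibility reduces to disjoint-or-nested
    return not (a & b) or (a | b) == a or (a | b) == b


def tree_from_splits(splits: Iterable[Iterable[str]], leaf_set: Iterable[str]) -> LabeledTree:
    """Unique unrooted tree whose nontrivial split set equals the input.

    Raises ``ValueError`` naming the offending pair if the splits are not
    pairwise compatible.
    """
    return LabeledTree.from_splits(leaf_set, splits)


def _tree_from_masks(masks: Iterable[int], labels: Sequence[str]) -> LabeledTree:
    return LabeledTree(labels, masks)


def strict_consensus(trees: TreeSet) -> LabeledTree:
    """Tree of the splits common to all input trees."""
    table = split_frequencies(trees)
    keep = [m for m, c in table.items() if c == table.n_trees]
    return _tree_from_masks(keep, table.labels)


def majority_consensus(trees: TreeSet) -> LabeledTree:
    """Tree of the splits present in strictly more than 50% of the inputs."""
    table = split_frequencies(trees)
    half = table.n_trees / 2.0
    keep = [m for m, c in table.items() if c > half]
    return _tree_from_masks(keep, table.labels)


def _side_sort_key(mask: int, labels: Sequence[str]) -> tuple:
    return tuple(sorted(labels[i] for i in range(len(labels)) if mask >> i & 1))


def extended_majority_consensus(trees: TreeSet) -> LabeledTree:
    """Greedy (extended majority rule) consensus.

    Majority splits are accepted first; the residual splits are then scanned
    in decreasing frequency (ties by ascending sorted side labels) and each
    is kept iff compatible with all splits accepted so far.
    """
    table = split_frequencies(trees)
    labels = table.labels
    half = table.n_trees / 2.0
    accepted = [m for m, c in table.items() if c > half]
    residual = [(c, m) for m, c in table.items() if c <= half]
    residual.sort(key=lambda cm: (-cm[0], _side_sort_key(cm[1], labels)))
    for _, m in residual:
        if all(_masks_compatible(m, a) for a in accepted):
            accepted.append(m)
    return _tree_from_masks(accepted, labels)


_CONSENSUS_KINDS = {
    "strict": strict_consensus,
    "majority": majority_consensus,
    "extended": extended_majority_consensus,
}


def consensus_tree(trees: TreeSet, kind: str = "extended") -> LabeledTree:
    """Dispatch to one of the three consensus constructions."""
    try:
        fn = _CONSENSUS_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown consensus kind {kind!r}; expected one of "
                         f"{sorted(_CONSENSUS_KINDS)}") from None
    return fn(trees)
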