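"""Reading and writing Newick trees as unrooted leaf-labeled topologies.

A phylogenetic tree is treated purely topologically: an unrooted tree whose
leaves carry unique labels and whose internal nodes may be multifurcating.
Branch lengths, support values and internal-node labels are tolerated on
input and discarded, because every downstream computation (Robinson-Foulds
distances, consensus construction, clustering) depends only on the set of
nontrivial bipartitions (splits) the tree induces.

A topology is therefore stored canonically as its split set.  Each split is
represented as a bitmask over the sorted leaf labels, keeping the side that
does *not* contain the reference leaf (the lexicographically smallest
label).  Two :class:`LabeledTree` objects compare equal iff they are the
same unrooted topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy


class NewickParseError(ValueError):
    """Malformed Newick input; carries a character/column offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a precondition (e.g. duplicate labels)."""


class LeafSetMismatchError(ValueError):
    """Trees in a multi-tree input do not share one leaf-label set."""


def _mask_min_bit(mask: int) -> int:
    return (mask & -mask).bit_length() - 1


def _iter_bits(mask: int) -> Iterator[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


class LabeledTree:
    """An unrooted leaf-labeled topology, canonically encoded by its splits.

    Parameters
    ----------
    labels : sequence of str
        Leaf labels; stored sorted.  Must be unique.
    split_masks : iterable of int
        Nontrivial splits as bitmasks over the sorted labels.  Each mask is
        the side excluding bit 0 (the smallest label) with
        ``2 <= popcount <= n - 2``.
    """

    __slots__ = ("labels", "split_masks", "_index")

    def __init__(self, labels: Sequence[str], split_masks: Iterable[int]):
        labels = tuple(sorted(labels))
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if list(labels).count(l) > 1})
            raise TreeValidationError(f"duplicate leaf label(s): {', '.join(dup)}")
        if len(labels) < 2:
            raise TreeValidationError("a tree needs at least 2 leaves")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        masks = set()
        for m in split_masks:
            if m & 1:
                raise ValueError("canonical split mask must exclude the reference leaf (bit 0)")
            k = m.bit_count()
            if not (2 <= k <= n - 2):
                raise ValueError(f"split of size {k} is trivial for n={n}")
            masks.add(m)
        self.split_masks = frozenset(masks)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledTree):
            return NotImplemented
        return self.labels == other.labels and self.split_masks == other.split_masks

    def __hash__(self) -> int:
        return hash((self.labels, self.split_masks))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LabeledTree(n={self.n_leaves}, splits={len(self.split_masks)})"

    # -- split views -------------------------------------------------------
    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self._index[lab]
        return m

    def labels_of(self, mask: int) -> frozenset[str]:
        return frozenset(self.labels[i] for i in _iter_bits(mask))

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial splits as label sets (canonical side, reference leaf excluded)."""
        return frozenset(self.labels_of(m) for m in self.split_masks)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_splits(cls, leaf_set: Iterable[str], sides: Iterable[Iterable[str]]) -> "LabeledTree":
        """Build the unique tree whose nontrivial split set equals ``sides``.

        Sides may be given from either half of each bipartition; they are
        canonicalised.  Raises ``ValueError`` naming the first incompatible
        pair if the family is not pairwise compatible.
        """
        labels = tuple(sorted(leaf_set))
        index = {lab: i for i, lab in enumerate(labels)}
        full = (1 << len(labels)) - 1
        masks = []
        for side in sides:
            m = 0
            for lab in side:
                if lab not in index:
                    raise ValueError(f"split member {lab!r} not in leaf set")
                m |= 1 << index[lab]
            if m & 1:
                m = full & ~m
            masks.append(m)
        tree = cls(labels, masks)
        # verify compatibility (laminar family over canonical sides)
        ms = sorted(tree.split_masks, key=lambda m: (m.bit_count(), m))
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                if a & b and (a | b) != a and (a | b) != b:
                    raise ValueError(
                        f"incompatible splits: {sorted(tree.labels_of(a))} vs {sorted(tree.labels_of(b))}"
                    )
        return tree

    # -- serialisation -----------------------------------------------------
    def newick(self) -> str:
        """Canonical Newick string: children sorted by smallest descendant label."""
        children: dict[int, list[int]] = {}
        tops: list[int] = []
        # sides sorted by size descending; parent of a side is the smallest
        # strict superset already placed (laminar family -> containment forest)
        order = sorted(self.split_masks, key=lambda m: -m.bit_count())
        placed: list[int] = []
        parent: dict[int, int | None] = {}
        for m in order:
            par = None
            for cand in reversed(placed):  # smallest supersets were placed last
                if m & cand == m:
                    par = cand
                    break
            parent[m] = par
            placed.append(m)
        for m in order:
            children.setdefault(m, [])
            if parent[m] is None:
                tops.append(m)
            else:
                children[parent[m]].append(m)

        def covered(kids: list[int]) -> int:
            c = 0
            for k in kids:
                c |= k
            return c

        def render(mask_or_leaf, is_leaf: bool) -> tuple[int, str]:
            if is_leaf:
                return mask_or_leaf, self.labels[mask_or_leaf]
            kids = children[mask_or_leaf]
            parts = [render(k, False) for k in kids]
            for bit in _iter_bits(mask_or_leaf & ~covered(kids)):
                parts.append((bit, self.labels[bit]))
            parts.sort(key=lambda p: p[0])
            return _mask_min_bit(mask_or_leaf), "(" + ",".join(p[1] for p in parts) + ")"

        full = (1 << self.n_leaves) - 1
        root_parts = [render(m, False) for m in tops]
        for bit in _iter_bits(full & ~covered(tops)):
            root_parts.append((bit, self.labels[bit]))
        root_parts.sort(key=lambda p: p[0])
        return "(" + ",".join(p[1] for p in root_parts) + ");"


@dataclass
class TreeSet:
    """An ordered collection of trees on one shared leaf set.

    The position of each tree in ``trees`` is the identity used by every
    downstream module (distance matrices, partitions, labels files).
    """

    trees: list[LabeledTree]
    source_index: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.trees:
            raise ValueError("TreeSet needs at least one tree")
        ref = self.trees[0].leaf_set
        for i, t in enumerate(self.trees):
            if t.leaf_set != ref:
                diff = sorted(t.leaf_set ^ ref)
                raise LeafSetMismatchError(
                    f"tree {i} has a different leaf set (symmetric difference: {', '.join(diff)})"
                )
        if not self.source_index:
            self.source_index = list(range(len(self.trees)))

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.trees[0].leaf_set

    @property
    def n_leaves(self) -> int:
        return self.trees[0].n_leaves

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[LabeledTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> LabeledTree:
        return self.trees[i]


# ---------------------------------------------------------------------------
# parsing


def _tree_from_dendropy(dtree: "dendropy.Tree") -> LabeledTree:
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        seen, dup = set(), set()
        for l in leaves:
            (dup if l in seen else seen).add(l)
        raise TreeValidationError(f"duplicate leaf label(s): {', '.join(sorted(dup))}")
    labels = tuple(sorted(leaves))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    full = (1 << n) - 1
    masks: set[int] = set()

    def walk(node) -> int:
        if node.is_leaf():
            return 1 << index[node.taxon.label]
        m = 0
        for ch in node.child_nodes():
            m |= walk(ch)
        side = (full & ~m) if (m & 1) else m
        if 2 <= side.bit_count() <= n - 2:
            masks.add(side)
        return m

    walk(dtree.seed_node)
    return LabeledTree(labels, masks)


def parse_newick(text: str) -> LabeledTree:
    """Parse one Newick statement into a :class:`LabeledTree`.

    Rooted inputs are unrooted (a degree-2 root contributes no extra split);
    branch lengths, support values and internal labels are discarded; quoted
    labels are unquoted.  Raises :class:`NewickParseError` on syntax errors
    (with a character offset when available) and
    :class:`TreeValidationError` on duplicate leaf labels.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick string")
    if not stripped.endswith(";"):
        stripped += ";"
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from None
    return _tree_from_dendropy(dtree)


def _iter_newick_statements(text: str) -> Iterator[str]:
    """Split a multi-tree text into ';'-terminated statements.

    Quoted labels are respected, so a quoted ';' does not terminate a tree.
    """
    buf: list[str] = []
    in_quote = False
    for ch in text:
        if ch == "'":
            in_quote = not in_quote
        buf.append(ch)
        if ch == ";" and not in_quote:
            stmt = "".join(buf).strip()
            if stmt and stmt != ";":
                yield stmt
            buf = []
    tail = "".join(buf).strip()
    if tail:
        yield tail + ";"


def read_treeset(path) -> TreeSet:
    """Read a multi-tree Newick file into a :class:`TreeSet`.

    Trees may be separated by newlines and/or semicolons; blank lines are
    ignored.  All trees must share one leaf-label set; on mismatch the error
    names the first offending tree index and the differing labels.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    trees: list[LabeledTree] = []
    for i, stmt in enumerate(_iter_newick_statements(text)):
        try:
            trees.append(parse_newick(stmt))
        except (NewickParseError, TreeValidationError) as exc:
            raise type(exc)(f"tree {i}: {exc}") from None
    if not trees:
        raise ValueError("no trees found in input")
    return TreeSet(trees)


def write_newick(tree: LabeledTree) -> str:
    """Canonical Newick serialisation of a tree (see :meth:`LabeledTree.newick`)."""
    return tree.newick()


def write_treeset(trees: Iterable[LabeledTree], path) -> None:
    """Write trees one Newick statement per line."""
    if hasattr(path, "write"):
        fh = path
        close = False
    else:
        fh = open(path, "w", encoding="utf-8")
        close = True
    try:
        for t in trees:
            fh.write(t.newick() + "\n")
    finally:
        if close:
            fh.close()
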