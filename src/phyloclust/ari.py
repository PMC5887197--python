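"""Adjusted Rand Index between two partitions of the same objects.

The ARI is the chance-corrected Rand index: pair counts are summarised in a
contingency table and the index is

    ARI = (sum_ij C(n_ij,2) - E) / (max - E),
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2,

with a_i, b_j the row/column sums.  Values lie in [-1, 1]; identical
partitions (up to cluster relabelling) score exactly 1.

All binomial terms use exact integer arithmetic, with a single exact
rational division at the end, so agreement with reference implementations
holds to full double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np


@dataclass
class ContingencyTable:
    counts: np.ndarray  # r x s, n_ij = |X_i n Y_j|
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int
    row_ids: list
    col_ids: list


def contingency_table(x: Sequence, y: Sequence) -> ContingencyTable:
    """Cross-tabulation n_ij = number of objects shared by cluster X_i and Y_j."""
    if len(x) != len(y):
        raise ValueError(f"label sequences differ in length: {len(x)} vs {len(y)}")
    if len(x) == 0:
        raise ValueError("need at least one object")
    row_ids = sorted(set(x), key=lambda v: (str(type(v)), v))
    col_ids = sorted(set(y), key=lambda v: (str(type(v)), v))
    ri = {v: i for i, v in enumerate(row_ids)}
    ci = {v: j for j, v in enumerate(col_ids)}
    counts = np.zeros((len(row_ids), len(col_ids)), dtype=np.int64)
    for xv, yv in zip(x, y):
        counts[ri[xv], ci[yv]] += 1
    return ContingencyTable(counts=counts, row_sums=counts.sum(axis=1),
                            col_sums=counts.sum(axis=0), n=len(x),
                            row_ids=row_ids, col_ids=col_ids)


def adjusted_rand_index(x: Sequence, y: Sequence) -> float:
    """Exact ARI of two label sequences; invariant to cluster relabelling."""
    if len(x) < 2:
        raise ValueError("ARI needs at least 2 objects")
    t = contingency_table(x, y)
    sum_ij = sum(comb(int(v), 2) for v in t.counts.ravel())
    sum_a = sum(comb(int(v), 2) for v in t.row_sums)
    sum_b = sum(comb(int(v), 2) for v in t.col_sums)
    pairs = comb(t.n, 2)
    expected = Fraction(sum_a * sum_b, pairs)
    maximum = Fraction(sum_a + sum_b, 2)
    if maximum == expected:
        # both partitions all-singletons or both one cluster: identical, ARI 1
        return 1.0
    return float(Fraction(sum_ij) - expected) / float(maximum - expected)


def read_labels(path) -> list[int]:
    """Read a one-integer-label-per-line file aligned with tree order."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    labels = [int(line.strip()) for line in lines if line.strip()]
    if not labels:
        raise ValueError("empty label file")
    return labels
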