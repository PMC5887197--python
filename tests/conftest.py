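import numpy as np
import pytest

import phyloclust as pc
from phyloclust.clustering import Partition
from phyloclust.tree_splits import DistanceMatrix


@pytest.fixture
def five_leaf_pair():
    """Two 5-leaf trees sharing exactly one split ({D,E}); RF distance 2."""
    t1 = pc.parse_newick("((A,B),C,(D,E));")
    t2 = pc.parse_newick("((A,C),B,(D,E));")
    return t1, t2


@pytest.fixture
def micro():
    """Four objects with within-pair distance 2 and cross-pair distance 8.

    The true 2-clustering {0,1},{2,3} has objective 4, SH 0.875, CH 8.
    """
    v = np.array([[0, 2, 8, 8],
                  [2, 0, 8, 8],
                  [8, 8, 0, 2],
                  [8, 8, 2, 0]], dtype=np.int64)
    d = DistanceMatrix(values=v, kind="rf", n_leaves=7)
    p = Partition(labels=np.array([0, 0, 1, 1]), medoids=(0, 2), K=2)
    return d, p


def two_cluster_partitions(n):
    """All assignments of n objects into exactly 2 nonempty unlabeled clusters."""
    out = []
    for code in range(1, 2 ** (n - 1)):  # object 0 fixed in cluster 0
        labels = [0] + [(code >> i) & 1 for i in range(n - 1)]
        if 1 in labels:
            out.append(labels)
    return out
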