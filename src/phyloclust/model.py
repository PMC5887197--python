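"""Model/Results front end for tree clustering.

:class:`TreeClustering` is built from a tree set (or a Newick file) and
holds the precomputed RF distance matrix; :meth:`TreeClustering.fit`
searches a range of K with k-medoids and returns a
:class:`TreeClusteringResults` carrying the selected partition, per-K
validity scores, medoid trees and per-cluster consensus trees, with a
``summary()`` in the familiar fitted-model style.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from . import consensus as _consensus
from .ari import adjusted_rand_index
from .newick_io import LabeledTree, TreeSet, read_treeset, write_newick
from .tree_splits import DistanceMatrix, pairwise_rf_matrix
from .validity import KSelectionReport, select_k


class TreeClustering:
    """Tree-clustering model over a collection of phylogenies on one leaf set.

    Parameters
    ----------
    trees : TreeSet
        Input trees; their order is the object identity in all outputs.
    distance : {"rf", "rf2"}
        Plain or squared Robinson-Foulds distance; the choice propagates
        into the clustering objective and both validity indices.
    """

    def __init__(self, trees: TreeSet, distance: str = "rf"):
        if distance not in ("rf", "rf2"):
            raise ValueError("distance must be 'rf' or 'rf2'")
        self.trees = trees
        self.distance = distance
        self.distance_matrix: DistanceMatrix = pairwise_rf_matrix(
            trees, squared=(distance == "rf2"))

    @classmethod
    def from_newick(cls, path, distance: str = "rf") -> "TreeClustering":
        return cls(read_treeset(path), distance=distance)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_leaves(self) -> int:
        return self.trees.n_leaves

    def fit(self, k: int | None = None, k_range: tuple[int, int] = (2, 10),
            index: str = "sh", n_starts: int = 30, max_iter: int = 100,
            seed: int | None = None,
            consensus_kind: str = "extended") -> "TreeClusteringResults":
        """Cluster the trees; select K by the validity index unless fixed.

        With ``k`` given, only that K is fitted (the index is still
        computed and reported); otherwise every K in ``k_range`` is fitted
        and the index argmax is selected.
        """
        k_min, k_max = (k, k) if k is not None else k_range
        report = select_k(self.distance_matrix, index_kind=index, k_min=k_min,
                          k_max=k_max, n_starts=n_starts, max_iter=max_iter,
                          seed=seed)
        return TreeClusteringResults(self, report, index=index,
                                     consensus_kind=consensus_kind,
                                     n_starts=n_starts, seed=seed)


class TreeClusteringResults:
    """Fitted tree clustering: selected K, partition, scores, consensus trees."""

    def __init__(self, model: TreeClustering, report: KSelectionReport,
                 index: str, consensus_kind: str, n_starts: int,
                 seed: int | None):
        self.model = model
        self.report = report
        self.index = index
        self.consensus_kind = consensus_kind
        self.n_starts = n_starts
        self.seed = seed
        self.best_k: int = report.best_K
        self.partition = report.best_partition
        self.labels_: np.ndarray = report.best_partition.labels
        self.medoids_: tuple[int, ...] = report.best_partition.medoids
        self.objective_: float = report.results[report.best_K].objective
        self.score_: float = report.scores[report.best_K].value

    # -- derived artefacts -------------------------------------------------
    def scores_table(self) -> pd.DataFrame:
        """Per-K table of objective and validity score; selected K flagged."""
        return pd.DataFrame(self.report.as_rows())

    def cluster_members(self, k: int) -> list[int]:
        return [int(i) for i in self.partition.members(k)]

    def cluster_sizes(self) -> list[int]:
        return self.partition.sizes()

    def medoid_trees(self) -> list[LabeledTree]:
        return [self.model.trees[m] for m in self.medoids_]

    def consensus_trees(self, kind: str | None = None) -> list[LabeledTree]:
        """One consensus tree per cluster (default: the fitted consensus kind)."""
        kind = kind or self.consensus_kind
        out = []
        for k in range(self.best_k):
            members = [self.model.trees[i] for i in self.cluster_members(k)]
            out.append(_consensus.consensus_tree(TreeSet(members), kind=kind))
        return out

    def ari_against(self, true_labels: Sequence) -> float:
        """Adjusted Rand Index of the fitted partition against reference labels."""
        return adjusted_rand_index(list(true_labels), list(self.labels_))

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Tree clustering (k-medoids, {} distance)".format(
                "squared RF" if m.distance == "rf2" else "RF"),
            "=" * 56,
            f"No. trees:            {m.n_trees}",
            f"No. leaves:           {m.n_leaves}",
            f"Validity index:       {self.index.upper()}",
            f"Selected K:           {self.best_k}",
            f"Objective (OF_med):   {self.objective_:g}",
            f"{self.index.upper()} at selected K:    {self.score_:.4f}",
            f"Cluster sizes:        {self.cluster_sizes()}",
            f"Medoid tree indices:  {list(self.medoids_)}",
            "-" * 56,
            "K scan:",
        ]
        for row in self.report.as_rows():
            mark = "  <- selected" if row["selected"] else ""
            lines.append(f"  K={row['K']:<3d} objective={row['objective']:<10g} "
                         f"{self.index}={row[self.index]:.4f}{mark}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write partition, per-K report, consensus Newick files and a JSON log."""
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "partition.tsv"), "w") as fh:
            fh.write("tree_index\tcluster_id\n")
            for i, lab in enumerate(self.labels_):
                fh.write(f"{i}\t{int(lab) + 1}\n")
        # one label per line, aligned with tree order: the format `ari` reads
        with open(os.path.join(outdir, "cluster_labels.txt"), "w") as fh:
            for lab in self.labels_:
                fh.write(f"{int(lab) + 1}\n")
        self.scores_table().assign(
            medoids=lambda df: df["medoids"].map(lambda ms: ",".join(map(str, ms)))
        ).to_csv(os.path.join(outdir, "k_scan.tsv"), sep="\t", index=False)
        for k, tree in enumerate(self.consensus_trees()):
            with open(os.path.join(outdir, f"cluster{k + 1}.nwk"), "w") as fh:
                fh.write(write_newick(tree) + "\n")
        log = {
            "n_trees": self.model.n_trees,
            "n_leaves": self.model.n_leaves,
            "distance": self.model.distance,
            "index": self.index,
            "consensus_kind": self.consensus_kind,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "best_k": self.best_k,
            "objective": self.objective_,
            "score": self.score_,
            "cluster_sizes": self.cluster_sizes(),
            "medoids": list(self.medoids_),
        }
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(log, fh, indent=2)
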