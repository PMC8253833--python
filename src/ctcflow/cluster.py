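"""Hierarchical clustering convention used across the pipeline.

Cells are clustered on Euclidean distances of log2(x + 1) profiles.  The
linkage defaults to Ward; average and complete are available.  The
dendrogram wraps a scipy linkage matrix and supports cutting at k
clusters and Newick export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import ExpressionMatrix

LINKAGES = ("ward", "average", "complete")


@dataclass
class Dendrogram:
    """Merge tree over cells with heights."""

    linkage_matrix: np.ndarray
    labels: list[str]
    linkage: str
    distance: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k clusters; returns cell id -> cluster label (1..k)."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}]")
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hcluster_values(
    values: np.ndarray, labels: Sequence[str], linkage: str = "ward"
) -> Dendrogram:
    """Cluster rows of ``values`` (observations x features)."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two observations")
    dist = pdist(values, metric="euclidean")
    lm = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(linkage_matrix=lm, labels=[str(l) for l in labels], linkage=linkage)


def hcluster(
    matrix: ExpressionMatrix,
    cells: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    linkage: str = "ward",
) -> Dendrogram:
    """Cluster cells on Euclidean distance of log2(x + 1) expression."""
    sub = matrix.subset(genes=genes, cells=cells)
    return hcluster_values(np.log2(sub.values + 1.0).T, sub.cell_ids, linkage=linkage)
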