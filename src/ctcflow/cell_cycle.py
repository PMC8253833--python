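"""G1/S and G2/M scoring and cycling/noncycling classification.

Relative expression of gene i in cell j is the row-centered log value
E[i, j] = log2(x[i, j] + 1) − mean_j log2(x[i, ·] + 1), so each gene
averages to zero across the scored cells.  A cell's G1/S (resp. G2/M)
score is the mean E over the replication (resp. mitosis) signature; a
cell is called cycling either by 2-cluster hierarchical clustering of the
(G1/S, G2/M) score plane (Ward/Euclidean, the cluster with the larger
mean max-score is the cycling one) or by a simple threshold on
max(G1/S, G2/M).

The package ships a standard 42-gene replication and 54-gene mitosis
signature (single-cell-derived, widely used); any GMT with sets named
G1S and G2M can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import hcluster_values
from .datamodel import CellRecord, ExpressionMatrix, GeneSetCollection
from .io import read_gmt

log = logging.getLogger("ctcflow")


@dataclass
class CycleScore:
    cell_id: str
    g1s_score: float
    g2m_score: float
    cycling: bool = False
    site: str = "NA"

    @property
    def max_score(self) -> float:
        return max(self.g1s_score, self.g2m_score)


def builtin_cycle_sets() -> GeneSetCollection:
    """The packaged 42-gene G1/S and 54-gene G2/M signature."""
    ref = resources.files("ctcflow.data").joinpath("cell_cycle_signature.gmt")
    with resources.as_file(ref) as path:
        return read_gmt(path)


def relative_expression(matrix: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Row-centered log2(x + 1) for the listed genes (genes x cells).

    Genes absent from the matrix are dropped with a warning; every row of
    the result sums to zero across cells.
    """
    present = [g for g in genes if g in set(matrix.gene_ids)]
    missing = [g for g in genes if g not in set(matrix.gene_ids)]
    if missing:
        log.warning("%d signature gene(s) not in matrix (e.g. %s)", len(missing), missing[:5])
    if not present:
        raise ValueError("none of the listed genes are present in the matrix")
    if matrix.n_cells < 2:
        raise ValueError("need at least two cells to center relative expression")
    sub = matrix.subset(genes=present)
    log2 = np.log2(sub.values + 1.0)
    centered = log2 - log2.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=sub.gene_ids, columns=sub.cell_ids)


def cycle_scores(
    matrix: ExpressionMatrix,
    g1s_set: Sequence[str] | None = None,
    g2m_set: Sequence[str] | None = None,
    cells: Sequence[CellRecord] | None = None,
) -> list[CycleScore]:
    """Per-cell mean relative expression over each phase signature.

    Defaults to the packaged signatures.  Centering is over the cell set
    of the matrix passed in; subset the matrix first for per-site
    centering.
    """
    if g1s_set is None or g2m_set is None:
        sets = builtin_cycle_sets()
        g1s_set = g1s_set if g1s_set is not None else sets["G1S"]
        g2m_set = g2m_set if g2m_set is not None else sets["G2M"]
    site_of = {c.cell_id: c.site.value for c in cells} if cells else {}
    scores = []
    e_g1s = relative_expression(matrix, list(g1s_set)).mean(axis=0)
    e_g2m = relative_expression(matrix, list(g2m_set)).mean(axis=0)
    for cid in matrix.cell_ids:
        scores.append(
            CycleScore(
                cell_id=cid,
                g1s_score=float(e_g1s[cid]),
                g2m_score=float(e_g2m[cid]),
                site=site_of.get(cid, "NA"),
            )
        )
    return scores


def classify_cycling(
    scores: Sequence[CycleScore],
    method: str = "hclust2",
    threshold: float = 1.0,
) -> list[CycleScore]:
    """Set cycling flags; returns new CycleScore objects.

    method='hclust2': Ward/Euclidean clustering of cells on the combined
    cycling activity max(g1s, g2m) cut at two clusters; the cluster whose
    mean activity is larger is called cycling.  (Clustering the raw 2-D
    score plane instead tends to split cycling cells by *phase* — the
    plane is three-lobed — so the cut is taken on the single activity
    axis, which is the quantity that defines "cycling".)
    method='threshold': cycling iff max(g1s, g2m) >= threshold.
    """
    if method == "threshold":
        return [
            CycleScore(s.cell_id, s.g1s_score, s.g2m_score,
                       cycling=s.max_score >= threshold, site=s.site)
            for s in scores
        ]
    if method != "hclust2":
        raise ValueError("method must be 'hclust2' or 'threshold'")
    if len(scores) < 2:
        raise ValueError("hclust2 needs at least two cells")
    pts = np.array([[s.max_score] for s in scores])
    if np.allclose(pts, pts[0]):
        log.warning("all cells identical in score space; calling all noncycling")
        return [
            CycleScore(s.cell_id, s.g1s_score, s.g2m_score, cycling=False, site=s.site)
            for s in scores
        ]
    dend = hcluster_values(pts, [s.cell_id for s in scores], linkage="ward")
    assign = dend.cut(2)
    max_scores = {s.cell_id: s.max_score for s in scores}
    cluster_means = {
        c: float(np.mean([max_scores[cid] for cid, cc in assign.items() if cc == c]))
        for c in set(assign.values())
    }
    cycling_cluster = max(cluster_means, key=lambda c: (cluster_means[c], -c))
    return [
        CycleScore(s.cell_id, s.g1s_score, s.g2m_score,
                   cycling=assign[s.cell_id] == cycling_cluster, site=s.site)
        for s in scores
    ]


def site_proportions(scores: Sequence[CycleScore]) -> dict[str, float]:
    """Percent of cycling cells per site, rounded to one decimal."""
    df = pd.DataFrame(
        {"site": [s.site for s in scores], "cycling": [s.cycling for s in scores]}
    )
    out = {}
    for site, grp in df.groupby("site", sort=False):
        out[site] = round(float(100.0 * grp["cycling"].mean()), 1)
    return out


def scores_to_frame(scores: Sequence[CycleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in scores],
            "site": [s.site for s in scores],
            "g1s_score": [s.g1s_score for s in scores],
            "g2m_score": [s.g2m_score for s in scores],
            "cycling": [s.cycling for s in scores],
        }
    )
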