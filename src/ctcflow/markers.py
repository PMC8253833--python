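"""Staged differential-expression cascade and gene-set enrichment.

The cascade mirrors a conservative marker-calling recipe for small
FPKM/CPM cohorts:

1. prefilter — drop genes with CPM < 1 in more than ``max_low_samples``
   samples (scale-dependent; literal default 2, exposed as a parameter);
2. test — per gene, two-sided Wilcoxon rank-sum on log2(x + 1); log2 fold
   change is the difference of group means of log2(x + 1); BH FDR across
   tested genes; *initial* DEGs satisfy |log2FC| > 1, P < 0.05, FDR < 0.05;
3. refine — *potential* DEGs additionally show a group-mean log2-FPKM fold
   change > 1 toward the up-group and are expressed (FPKM > 1) in at least
   90% of up-group cells; a confirmatory rank-sum P < 0.05 then promotes
   them to *final* markers.

Stage nesting (final ⊆ potential ⊆ initial ⊆ tested) is asserted on every
run.  Enrichment of a final gene list against named sets uses the
upper-tail hypergeometric test with BH correction across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .datamodel import ExpressionMatrix, GeneSetCollection

log = logging.getLogger("ctcflow")

STAGES = ["filtered_out", "tested", "initial", "potential", "final"]
_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}


@dataclass
class MarkerTable:
    """Per-gene cascade results for one contrast (group A vs group B)."""

    table: pd.DataFrame  # gene_id, mean_a, mean_b, log2fc, p, q, expr_frac_a, expr_frac_b, stage
    contrast: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        self._assert_nesting()

    def _assert_nesting(self) -> None:
        ranks = self.table["stage"].map(_STAGE_RANK)
        assert not ranks.isna().any(), "unknown stage label"
        # nesting is structural: stage is a single ordered label per gene,
        # so final ⊆ potential ⊆ initial holds by construction; verify the
        # label set anyway
        assert set(self.table["stage"]) <= set(STAGES)

    def at_stage(self, stage: str) -> list[str]:
        """Gene ids at or above the given stage."""
        want = _STAGE_RANK[stage]
        ranks = self.table["stage"].map(_STAGE_RANK)
        return self.table.loc[ranks >= want, "gene_id"].tolist()

    def summary(self) -> dict:
        counts = {s: int((self.table["stage"].map(_STAGE_RANK) >= r).sum())
                  for s, r in _STAGE_RANK.items() if s != "filtered_out"}
        counts["filtered_out"] = int((self.table["stage"] == "filtered_out").sum())
        return {"contrast": self.contrast, "n_genes": len(self.table), "stages": counts}


def as_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each cell to counts-per-million and retag the unit."""
    colsum = matrix.values.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("cannot CPM-normalize a cell with zero total signal")
    return ExpressionMatrix(
        values=matrix.values / colsum * 1e6,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        unit="CPM",
    )


def cpm_prefilter(matrix: ExpressionMatrix, max_low_samples: int = 2) -> np.ndarray:
    """Boolean keep-mask: gene removed iff CPM < 1 in more than
    ``max_low_samples`` samples."""
    matrix.require_unit("CPM")
    n_low = (matrix.values < 1.0).sum(axis=1)
    return n_low <= max_low_samples


def differential_test(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "A_vs_B",
    gene_mask: np.ndarray | None = None,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> MarkerTable:
    """Per-gene rank-sum test with BH FDR and the *initial* stage call.

    log2FC is mean_a − mean_b of log2(x + 1); positive means up in A.
    ``gene_mask`` (e.g. from :func:`cpm_prefilter`) marks genes to test;
    masked-out genes are carried as stage ``filtered_out``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two cells")
    ia, ib = matrix.cell_index(group_a), matrix.cell_index(group_b)
    log2 = matrix.log2p1()
    if gene_mask is None:
        gene_mask = np.ones(matrix.n_genes, dtype=bool)
    gene_mask = np.asarray(gene_mask, dtype=bool)
    if gene_mask.shape != (matrix.n_genes,):
        raise ValueError("gene_mask length does not match the matrix")

    a, b = log2[np.ix_(gene_mask, ia)], log2[np.ix_(gene_mask, ib)]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    p = stats.rank_sum_matrix(a, b)
    q = stats.bh_fdr(p)
    initial = (np.abs(lfc) > lfc_min) & (p < p_max) & (q < q_max)

    fpkm_a = matrix.values[np.ix_(gene_mask, ia)]
    fpkm_b = matrix.values[np.ix_(gene_mask, ib)]
    expr_a = (fpkm_a > 1.0).mean(axis=1)
    expr_b = (fpkm_b > 1.0).mean(axis=1)

    table = pd.DataFrame({"gene_id": matrix.gene_ids})
    table["mean_a"] = np.nan
    table["mean_b"] = np.nan
    table["log2fc"] = np.nan
    table["p"] = np.nan
    table["q"] = np.nan
    table["expr_frac_a"] = np.nan
    table["expr_frac_b"] = np.nan
    table["stage"] = "filtered_out"
    idx = np.where(gene_mask)[0]
    table.loc[idx, "mean_a"] = mean_a
    table.loc[idx, "mean_b"] = mean_b
    table.loc[idx, "log2fc"] = lfc
    table.loc[idx, "p"] = p
    table.loc[idx, "q"] = q
    table.loc[idx, "expr_frac_a"] = expr_a
    table.loc[idx, "expr_frac_b"] = expr_b
    table.loc[idx, "stage"] = np.where(initial, "initial", "tested")
    return MarkerTable(table=table, contrast=contrast,
                       group_a=list(group_a), group_b=list(group_b))


def refine_upregulated(
    marker_table: MarkerTable,
    matrix: ExpressionMatrix,
    expressed_min_fraction: float = 0.90,
    expressed_fpkm: float = 1.0,
    confirm_p_max: float = 0.05,
) -> MarkerTable:
    """Promote *initial* DEGs to *potential* and *final* marker stages.

    potential: group-mean log2(FPKM + 1) fold change > 1 toward the
    up-group AND expressed (FPKM > ``expressed_fpkm``) in at least
    ``expressed_min_fraction`` of up-group cells.  final: a confirmatory
    rank-sum test on log2(FPKM + 1) with P < ``confirm_p_max``.
    """
    matrix.require_unit("FPKM")
    ia = matrix.cell_index(marker_table.group_a)
    ib = matrix.cell_index(marker_table.group_b)
    log2 = matrix.log2p1()
    table = marker_table.table.copy()
    gi = matrix.gene_index(table["gene_id"].tolist())

    initial_rows = table.index[table["stage"].map(_STAGE_RANK) >= _STAGE_RANK["initial"]]
    for row in initial_rows:
        g = gi[row]
        va, vb = log2[g, ia], log2[g, ib]
        lfc = va.mean() - vb.mean()
        up_cols = ia if lfc > 0 else ib
        fpkm_fc = abs(lfc)
        expressed = (matrix.values[g, up_cols] > expressed_fpkm).mean()
        stage = "initial"
        if fpkm_fc > 1.0 and expressed >= expressed_min_fraction:
            stage = "potential"
            confirm_p = stats.wilcoxon_rank_sum(va, vb).p_value
            if confirm_p < confirm_p_max:
                stage = "final"
        table.loc[row, "stage"] = stage
    return MarkerTable(table=table, contrast=marker_table.contrast,
                       group_a=marker_table.group_a, group_b=marker_table.group_b)


def run_cascade(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "A_vs_B",
    max_low_samples: int = 2,
    **kwargs,
) -> MarkerTable:
    """Full cascade: CPM prefilter → rank-sum/BH initial call → FPKM refine."""
    matrix.require_unit("FPKM")
    used = matrix.subset(cells=[*group_a, *group_b])
    keep = cpm_prefilter(as_cpm(used), max_low_samples=max_low_samples)
    initial = differential_test(matrix, group_a, group_b, contrast=contrast,
                                gene_mask=_expand_mask(matrix, used, keep), **kwargs)
    return refine_upregulated(initial, matrix)


def _expand_mask(full: ExpressionMatrix, used: ExpressionMatrix, keep: np.ndarray) -> np.ndarray:
    mask = np.zeros(full.n_genes, dtype=bool)
    mask[full.gene_index(used.gene_ids)] = keep
    return mask


def enrich(
    query_genes: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str] | int | None = None,
) -> pd.DataFrame:
    """Hypergeometric overlap of a query gene list with each named set.

    ``universe`` may be an explicit gene list, a count, or None (falls
    back to the collection's universe).  Overlaps and set sizes are
    counted within the universe when it is a list.  BH correction is
    applied across sets; rows sorted by (q, p).
    """
    query = list(dict.fromkeys(query_genes))
    if not query:
        raise ValueError("empty query gene list")
    if universe is None:
        universe = sets.universe
        if universe is None:
            raise ValueError("no universe given and the collection has none")
    if isinstance(universe, int):
        universe_n = universe
        universe_set = None
    else:
        universe_set = set(universe)
        universe_n = len(universe_set)
        outside = [g for g in query if g not in universe_set]
        if outside:
            raise ValueError(f"query gene(s) outside the universe: {outside[:5]}")
    rows = []
    qset = set(query)
    for name in sets.names():
        members = sets[name]
        if universe_set is not None:
            members = [g for g in members if g in universe_set]
        k = len(members)
        if k > universe_n:
            raise ValueError(f"set {name} larger than the universe")
        overlap = len(qset & set(members))
        res = stats.hypergeom_overlap(universe_n, k, len(query), overlap)
        rows.append((name, k, len(query), overlap, res.p_value))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "query_size", "overlap", "p"])
    df["q"] = stats.bh_fdr(df["p"].to_numpy())
    return df.sort_values(["q", "p", "set_name"], kind="stable").reset_index(drop=True)
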