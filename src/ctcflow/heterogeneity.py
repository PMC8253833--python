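"""Cell-to-cell transcriptional heterogeneity per vascular site.

The statistic: over the top-variance genes (variance of log2(FPKM + 1),
default top 2000), compute the Pearson correlation of every unordered
pair of CTCs within a site.  A site's heterogeneity is summarized by the
mean pairwise correlation — lower mean r means higher heterogeneity —
and sites are compared by testing their correlation distributions
against each other (two-sided Wilcoxon rank-sum by default; Welch's t as
an option, since both conventions are in circulation for this statistic).

Caveat (documented, deliberate): pairwise correlations that share a cell
are treated as independent observations by the tests, as is conventional
for this statistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .datamodel import CellClass, CellRecord, ExpressionMatrix, Site, align_metadata

log = logging.getLogger("ctcflow")


@dataclass
class HeterogeneityReport:
    selected_genes: list[str]
    pair_correlations: dict[str, np.ndarray]   # site -> vector of pairwise r
    mean_r: dict[str, float]
    comparisons: pd.DataFrame                  # site_a, site_b, statistic, p, method
    grouping: str
    dropped_pairs: dict[str, int] = field(default_factory=dict)
    excluded_sites: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "grouping": self.grouping,
            "n_selected_genes": len(self.selected_genes),
            "mean_r": self.mean_r,
            "n_pairs": {s: int(v.size) for s, v in self.pair_correlations.items()},
            "dropped_pairs": self.dropped_pairs,
            "excluded_sites": self.excluded_sites,
        }


def select_variable_genes(
    matrix: ExpressionMatrix,
    k: int = 2000,
    cell_subset: Sequence[str] | None = None,
) -> list[str]:
    """Top-k genes by variance of log2(x + 1) across the included cells.

    All-constant genes are removed first; ties break deterministically by
    ascending gene id.  If fewer than k non-constant genes remain, all of
    them are returned with a warning.
    """
    sub = matrix.subset(cells=cell_subset) if cell_subset is not None else matrix
    log2 = np.log2(sub.values + 1.0)
    var = log2.var(axis=1, ddof=0)
    nonconstant = var > 0
    ids = np.array(sub.gene_ids)[nonconstant]
    var = var[nonconstant]
    if ids.size < k:
        log.warning("only %d non-constant genes available (k=%d)", ids.size, k)
        k = ids.size
    # sort by descending variance, ties by ascending gene id
    order = np.lexsort((ids, -var))
    return [str(g) for g in ids[order[:k]]]


def _pairwise_correlations(
    log2: np.ndarray, cols: Sequence[int], pair_groups: Sequence[str]
) -> tuple[np.ndarray, int]:
    """Pearson r for all within-group unordered column pairs.

    ``pair_groups`` restricts pairing (e.g. to within-patient pairs).
    Pairs involving a constant profile are dropped and counted.
    """
    vals = log2[:, list(cols)]
    n = vals.shape[1]
    sd = vals.std(axis=0)
    rs = []
    dropped = 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals.T) if n >= 2 else np.empty((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if pair_groups[i] != pair_groups[j]:
            continue
        if sd[i] == 0 or sd[j] == 0:
            dropped += 1
            continue
        rs.append(corr[i, j])
    return np.asarray(rs, dtype=float), dropped


def site_heterogeneity(
    matrix: ExpressionMatrix,
    cells: Sequence[CellRecord],
    genes: Sequence[str] | None = None,
    grouping: str = "pooled",
    patient: str | None = None,
    test: str = "wilcoxon",
    top_k: int = 2000,
    within_patient_pairs: bool = False,
) -> HeterogeneityReport:
    """Per-site pairwise-correlation distributions and site comparisons.

    grouping='pooled' analyses all CTCs, taking every unordered
    within-site pair (C(n_site, 2) correlations per site);
    ``within_patient_pairs=True`` restricts pairs to cells of the same
    patient, for cohorts where a patient effect would otherwise inflate
    apparent heterogeneity.  'single_patient' restricts the analysis to
    ``patient``.  Sites with fewer than two CTCs are excluded with a
    warning.  ``test`` in {'wilcoxon', 'welch', 'both'}.
    """
    if grouping not in ("pooled", "single_patient"):
        raise ValueError("grouping must be 'pooled' or 'single_patient'")
    if grouping == "single_patient" and patient is None:
        raise ValueError("single_patient grouping requires a patient id")
    ordered = align_metadata(matrix, cells, on_mismatch="intersect")
    ctcs = [
        c for c in ordered
        if c.cell_class is CellClass.CTC
        and (grouping == "pooled" or c.patient_id == patient)
    ]
    if genes is None:
        genes = select_variable_genes(
            matrix, k=top_k, cell_subset=[c.cell_id for c in ctcs]
        )
    sub = matrix.subset(genes=list(genes), cells=[c.cell_id for c in ctcs])
    log2 = np.log2(sub.values + 1.0)
    col_of = {cid: i for i, cid in enumerate(sub.cell_ids)}

    pair_corr: dict[str, np.ndarray] = {}
    dropped: dict[str, int] = {}
    excluded: list[str] = []
    for site in Site.circulation_order():
        members = [c for c in ctcs if c.site is site]
        if len(members) < 2:
            if members:
                excluded.append(site.value)
                log.warning("site %s has < 2 CTCs; excluded", site.value)
            continue
        cols = [col_of[c.cell_id] for c in members]
        groups = (
            [c.patient_id for c in members]
            if within_patient_pairs and grouping == "pooled"
            else ["all"] * len(members)
        )
        rs, n_drop = _pairwise_correlations(log2, cols, groups)
        if rs.size == 0:
            excluded.append(site.value)
            continue
        pair_corr[site.value] = rs
        dropped[site.value] = n_drop

    mean_r = {s: float(np.mean(v)) for s, v in pair_corr.items()}
    rows = []
    for sa, sb in itertools.combinations(pair_corr, 2):
        a, b = pair_corr[sa], pair_corr[sb]
        if test in ("wilcoxon", "both"):
            res = stats.wilcoxon_rank_sum(a, b)
            rows.append((sa, sb, res.statistic, res.p_value, res.method.value))
        if test in ("welch", "both"):
            res = stats.welch_t(a, b)
            rows.append((sa, sb, res.statistic, res.p_value, res.method.value))
    comparisons = pd.DataFrame(
        rows, columns=["site_a", "site_b", "statistic", "p", "method"]
    )
    return HeterogeneityReport(
        selected_genes=list(genes),
        pair_correlations=pair_corr,
        mean_r=mean_r,
        comparisons=comparisons,
        grouping=grouping,
        dropped_pairs=dropped,
        excluded_sites=excluded,
    )
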