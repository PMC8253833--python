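"""Cell- and gene-level quality-control filters.

A cell is kept only if it expresses at least 3000 genes (value > 0) and
carries more than one million uniquely mapped reads; the boundary
semantics are deliberate and documented (genes "< 3000" fails, reads
"<= 1e6" fails).  Detected-gene counts are recomputed from the matrix —
the matrix, not the metadata, is the source of truth — and a discrepancy
with the metadata is logged, never silently trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CellRecord, ExpressionMatrix, align_metadata

log = logging.getLogger("ctcflow")

MIN_GENES_DEFAULT = 3000
MIN_READS_DEFAULT = 1_000_000  # "1 M" read as 1e6


@dataclass
class QcReport:
    """Outcome of the cell filter: per-cell verdicts with reasons."""

    n_input: int
    n_pass: int
    flags: pd.DataFrame  # cell_id, detected_genes, mapped_reads, passed, reasons
    gene_mask: np.ndarray | None = None
    n_genes_kept: int | None = None

    def __post_init__(self) -> None:
        assert self.n_pass <= self.n_input
        failing = self.flags[~self.flags["passed"]]
        assert (failing["reasons"].str.len() > 0).all(), "failing cell without a reason"

    @property
    def passing_cells(self) -> list[str]:
        return self.flags.loc[self.flags["passed"], "cell_id"].tolist()

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass": self.n_pass,
            "n_fail": self.n_input - self.n_pass,
            "fail_reasons": self.flags.loc[~self.flags["passed"], "reasons"]
            .value_counts()
            .to_dict(),
            "n_genes_kept": self.n_genes_kept,
        }


def filter_cells(
    matrix: ExpressionMatrix | None,
    cells: Sequence[CellRecord],
    min_genes: int = MIN_GENES_DEFAULT,
    min_reads: int = MIN_READS_DEFAULT,
) -> QcReport:
    """Flag cells failing the detected-gene or mapped-read rule.

    A cell fails if detected_genes < ``min_genes`` OR mapped_reads <=
    ``min_reads``.  With a matrix given, detected_genes is recomputed as
    the number of genes with value > 0 (overriding the metadata, with a
    warning on discrepancy); with ``matrix=None`` the metadata counts are
    trusted.
    """
    if matrix is not None:
        ordered = align_metadata(matrix, cells)
        detected = (matrix.values > 0).sum(axis=0)
        mismatches = [
            c.cell_id for c, d in zip(ordered, detected) if c.detected_genes != int(d)
        ]
        if mismatches:
            log.warning(
                "detected_genes metadata disagrees with matrix for %d cell(s) "
                "(e.g. %s); matrix counts used",
                len(mismatches), mismatches[:3],
            )
    else:
        ordered = list(cells)
        detected = np.array([c.detected_genes for c in ordered])

    rows = []
    for c, d in zip(ordered, detected):
        reasons = []
        if int(d) < min_genes:
            reasons.append("genes")
        if c.mapped_reads <= min_reads:
            reasons.append("reads")
        rows.append(
            {
                "cell_id": c.cell_id,
                "detected_genes": int(d),
                "mapped_reads": c.mapped_reads,
                "passed": not reasons,
                "reasons": "+".join(reasons),
            }
        )
    flags = pd.DataFrame(rows)
    return QcReport(n_input=len(rows), n_pass=int(flags["passed"].sum()), flags=flags)


def filter_genes_expressed(
    matrix: ExpressionMatrix,
    min_fpkm: float = 1.0,
    min_cell_fraction: float = 0.10,
    cell_subset: Sequence[str] | None = None,
) -> np.ndarray:
    """Boolean gene mask: expressed (> min_fpkm) in > min_cell_fraction of cells.

    Both inequalities are strict.  ``cell_subset`` restricts the fraction
    to those cells (e.g. CTCs only) while the mask still indexes the full
    gene axis.
    """
    matrix.require_unit("FPKM")
    if cell_subset is not None:
        idx = matrix.cell_index(cell_subset)
        if idx.size == 0:
            raise ValueError("empty cell subset")
        values = matrix.values[:, idx]
    else:
        values = matrix.values
    if values.shape[1] == 0:
        raise ValueError("no cells to evaluate the expressed-gene rule on")
    frac = (values > min_fpkm).mean(axis=1)
    return frac > min_cell_fraction
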