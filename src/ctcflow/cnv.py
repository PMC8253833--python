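"""Expression-based copy-number inference against reference cells.

For each cell, log2(x + 1) expression is centered on the mean of a set
of diploid reference cells (leukocytes in a typical design), smoothed by
a centered moving average along genome order within each chromosome
(window 201 genes, truncated at chromosome edges — smoothing never
crosses a chromosome boundary), median-recentred per cell, and denoised
by a logistic weight that attenuates values near the reference baseline
more than values far from it:

    w(v) = 1 / (1 + exp(-s * (|v| / sigma_ref - m)))

with midpoint m = 2 (in units of the reference-cell SD of the smoothed
signal) and steepness s = 4 by default.  Genes with mean expression
below a cutoff (mean FPKM >= 1) are dropped before smoothing, as are
chromosomes with fewer than three retained genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GeneLocus, sort_loci

log = logging.getLogger("ctcflow")


@dataclass
class CnvProfile:
    """Genome-ordered smoothed relative-expression track for one cell."""

    cell_id: str
    gene_ids: list[str]       # genome order
    chromosomes: list[str]
    signal: np.ndarray        # denoised log2 signal, one value per retained gene
    raw_signal: np.ndarray    # pre-denoise smoothed signal
    is_reference: bool

    def segment_mean(self, genes: Sequence[str]) -> float:
        wanted = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        if not idx:
            raise ValueError("none of the requested genes are in the profile")
        return float(np.mean(self.signal[idx]))


def _moving_average_truncated(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with truncated edge windows."""
    n = values.shape[1]
    half = window // 2
    csum = np.cumsum(values, axis=1)
    csum = np.concatenate([np.zeros((values.shape[0], 1)), csum], axis=1)
    out = np.empty_like(values)
    for j in range(n):
        lo, hi = max(0, j - half), min(n, j + half + 1)
        out[:, j] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv(
    matrix: ExpressionMatrix,
    loci: Sequence[GeneLocus],
    reference_cells: Sequence[str],
    window: int = 201,
    mean_cutoff: float = 1.0,
    sd_amplifier_midpoint: float = 2.0,
    steepness: float = 4.0,
    min_chrom_genes: int = 3,
) -> list[CnvProfile]:
    """Per-cell smoothed, denoised relative-expression CNV profiles.

    ``mean_cutoff`` is the minimum mean raw expression (across all cells)
    for a gene to be retained.  ``window`` must be odd.  Genes without a
    locus are dropped with a warning.
    """
    matrix.require_unit("FPKM")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    ref = list(reference_cells)
    if not ref:
        raise ValueError("at least one reference cell is required")
    ref_idx = matrix.cell_index(ref)

    in_matrix = set(matrix.gene_ids)
    ordered = [l for l in sort_loci(list(loci)) if l.gene_id in in_matrix]
    uncovered = in_matrix - {l.gene_id for l in ordered}
    if uncovered:
        log.warning("%d gene(s) without a locus dropped", len(uncovered))

    # gene retention: mean raw expression across all cells
    row_of = {g: i for i, g in enumerate(matrix.gene_ids)}
    mean_expr = matrix.values.mean(axis=1)
    kept = [l for l in ordered if mean_expr[row_of[l.gene_id]] >= mean_cutoff]

    # drop undersized chromosomes
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in kept:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom in [c for c, ls in by_chrom.items() if len(ls) < min_chrom_genes]:
        log.warning("chromosome %s has < %d retained genes; dropped", chrom, min_chrom_genes)
        del by_chrom[chrom]
    if not by_chrom:
        raise ValueError("no chromosome retains enough genes")

    gene_order: list[GeneLocus] = [l for c in sorted(by_chrom) for l in by_chrom[c]]
    rows = np.array([row_of[l.gene_id] for l in gene_order])
    log2 = np.log2(matrix.values[rows, :] + 1.0)

    # reference-centering, then per-chromosome smoothing
    ref_mean = log2[:, ref_idx].mean(axis=1)
    signal = log2 - ref_mean[:, None]
    smoothed = np.empty_like(signal)
    pos = 0
    for chrom in sorted(by_chrom):
        n = len(by_chrom[chrom])
        smoothed[pos : pos + n, :] = _moving_average_truncated(
            signal[pos : pos + n, :].T, window
        ).T
        pos += n

    # per-cell median recentering
    smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)

    # logistic denoise in units of the reference-cell SD
    sigma_ref = float(smoothed[:, ref_idx].std())
    if sigma_ref == 0:
        sigma_ref = 1e-9
    weight = 1.0 / (
        1.0 + np.exp(-steepness * (np.abs(smoothed) / sigma_ref - sd_amplifier_midpoint))
    )
    denoised = smoothed * weight

    ref_set = set(ref)
    gene_ids = [l.gene_id for l in gene_order]
    chroms = [l.chromosome for l in gene_order]
    return [
        CnvProfile(
            cell_id=cid,
            gene_ids=gene_ids,
            chromosomes=chroms,
            signal=denoised[:, j].copy(),
            raw_signal=smoothed[:, j].copy(),
            is_reference=cid in ref_set,
        )
        for j, cid in enumerate(matrix.cell_ids)
    ]


def profiles_to_frame(profiles: Sequence[CnvProfile]) -> pd.DataFrame:
    """Long-format table (cell_id, chromosome, gene_id, signal, raw_signal)."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": p.cell_id,
                    "chromosome": p.chromosomes,
                    "gene_id": p.gene_ids,
                    "signal": p.signal,
                    "raw_signal": p.raw_signal,
                    "is_reference": p.is_reference,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
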