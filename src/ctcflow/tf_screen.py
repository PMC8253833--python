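"""Transcription-factor/target correlation screen.

Given a TF catalogue and a target gene, rank TFs by the Pearson
correlation of log2(x + 1) expression with the target across a chosen
cell subset, with a two-sided p-value from the t transform of r (exact
permutation p available for very small n), BH correction across TFs, and
an optional restriction to TFs at a given marker-cascade stage
(emulating "TFs upregulated in the tumor-cell compartment").  The screen
reports how many TFs are positively associated (r > 0, p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .datamodel import ExpressionMatrix
from .markers import MarkerTable

log = logging.getLogger("ctcflow")


@dataclass
class TfScreenResult:
    table: pd.DataFrame  # tf, r, p, q, rank (1 = highest r)
    target: str
    n_cells: int
    restricted_to_stage: str | None = None

    @property
    def n_positive(self) -> int:
        """TFs with r > 0 and p < 0.05."""
        return int(((self.table["r"] > 0) & (self.table["p"] < 0.05)).sum())

    def top(self, n: int = 1) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")

    def summary(self) -> dict:
        best = self.table.loc[self.table["rank"] == 1].iloc[0]
        return {
            "target": self.target,
            "n_tfs": len(self.table),
            "n_positive": self.n_positive,
            "top_tf": best["tf"],
            "top_r": float(best["r"]),
            "top_p": float(best["p"]),
            "restricted_to_stage": self.restricted_to_stage,
        }


def screen_tfs(
    matrix: ExpressionMatrix,
    tf_list: Sequence[str],
    target: str,
    cells: Sequence[str] | None = None,
    restrict_to: MarkerTable | None = None,
    restrict_stage: str = "final",
    exact_max_n: int = 0,
) -> TfScreenResult:
    """Correlation of each TF with the target gene across cells.

    TFs absent from the matrix are dropped with a warning; a TF constant
    across the cells gets r = NaN (undefined) and is ranked last.  A
    constant target is an error.
    """
    if target not in set(matrix.gene_ids):
        raise KeyError(f"target gene {target!r} not in matrix")
    present = set(matrix.gene_ids)
    tfs = [t for t in dict.fromkeys(tf_list) if t != target]
    missing = [t for t in tfs if t not in present]
    if missing:
        log.warning("%d TF(s) not in matrix dropped (e.g. %s)", len(missing), missing[:5])
    tfs = [t for t in tfs if t in present]
    if restrict_to is not None:
        allowed = set(restrict_to.at_stage(restrict_stage))
        tfs = [t for t in tfs if t in allowed]
    if not tfs:
        raise ValueError("no TFs left to screen")

    sub = matrix.subset(genes=[target, *tfs], cells=list(cells) if cells is not None else None)
    if sub.n_cells < 3:
        raise ValueError("need at least three cells")
    log2 = sub.log2p1()
    y = log2[0]
    if np.ptp(y) == 0:
        raise stats.UndefinedCorrelationError("target gene is constant across cells")

    rows = []
    for i, tf in enumerate(tfs, start=1):
        x = log2[i]
        if np.ptp(x) == 0:
            rows.append((tf, np.nan, np.nan))
            continue
        r, p = stats.pearson_test(x, y, exact_max_n=exact_max_n)
        rows.append((tf, r, p))
    df = pd.DataFrame(rows, columns=["tf", "r", "p"])
    valid = df["p"].notna()
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid.to_numpy()] = stats.bh_fdr(df.loc[valid, "p"].to_numpy())
    df["q"] = q
    # rank by descending r, NaNs last; ties broken by TF id for determinism
    df = df.sort_values(["r", "tf"], ascending=[False, True], na_position="last",
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return TfScreenResult(
        table=df,
        target=target,
        n_cells=sub.n_cells,
        restricted_to_stage=restrict_stage if restrict_to is not None else None,
    )
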