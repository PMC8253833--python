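"""Readers and writers for the on-disk formats the pipeline consumes.

Formats: TSV expression matrices (genes in rows, cell-id header), Matrix
Market triplets with row/column id sidecars, CSV cell metadata, GMT gene
sets, BED-like gene loci, and JSON run configs.  All text is UTF-8; gzip
compression is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    CellRecord,
    ExpressionMatrix,
    GeneLocus,
    GeneSetCollection,
    frame_to_records,
    records_to_frame,
    sort_loci,
)

log = logging.getLogger("ctcflow")


class ParseError(ValueError):
    """A file violated its expected format; message names the offending line."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, unit: str = "FPKM") -> ExpressionMatrix:
    """Read a genes-in-rows TSV matrix (first column gene id, header cell ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene id(s): {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate cell id(s): {dup[:5]}")
    values = df.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        raise ParseError(f"{path}: non-numeric or missing entries")
    if np.any(values < 0):
        raise ParseError(f"{path}: negative expression values")
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        unit=unit,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    unit: str = "FPKM",
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet with one-id-per-line sidecar files."""
    mat = scipy.io.mmread(str(mtx_path))
    values = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    with _open_text(genes_path) as fh:
        gene_ids = [line.strip() for line in fh if line.strip()]
    with _open_text(cells_path) as fh:
        cell_ids = [line.strip() for line in fh if line.strip()]
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise ParseError(
            f"{mtx_path}: matrix is {values.shape} but sidecars give "
            f"{len(gene_ids)} genes x {len(cell_ids)} cells"
        )
    if np.any(values < 0):
        raise ParseError(f"{mtx_path}: negative expression values")
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, unit=unit)


def write_expression_mtx(
    matrix: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(mtx_path), sparse, precision=6)
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n", encoding="utf-8")


def read_expression(path: str | Path, format: str = "tsv", unit: str = "FPKM",
                    genes_path: str | Path | None = None,
                    cells_path: str | Path | None = None) -> ExpressionMatrix:
    if format == "tsv":
        return read_expression_tsv(path, unit=unit)
    if format == "mtx_triplet":
        if genes_path is None or cells_path is None:
            base = Path(path)
            genes_path = genes_path or base.with_suffix(".genes.txt")
            cells_path = cells_path or base.with_suffix(".cells.txt")
        return read_expression_mtx(path, genes_path, cells_path, unit=unit)
    raise ValueError(f"unknown expression format: {format!r}")


# ---------------------------------------------------------------------------
# cell metadata
# ---------------------------------------------------------------------------

def read_cells_csv(path: str | Path) -> list[CellRecord]:
    # keep_default_na: "NA" is a legitimate site label, not a missing value
    df = pd.read_csv(path, keep_default_na=False)
    try:
        return frame_to_records(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_cells_csv(cells: Sequence[CellRecord], path: str | Path) -> None:
    records_to_frame(cells).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB members..."""
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g for g in fields[2:] if g]
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# gene loci (BED-like)
# ---------------------------------------------------------------------------

def read_loci(path: str | Path) -> list[GeneLocus]:
    """Read a BED-like file (chrom, start, end, gene_id) and genome-sort it."""
    loci: list[GeneLocus] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected chrom, start, end, gene_id")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                loci.append(GeneLocus(fields[3], fields[0], start, end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return sort_loci(loci)


def write_loci(loci: Sequence[GeneLocus], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for l in loci:
            fh.write(f"{l.chromosome}\t{l.start}\t{l.end}\t{l.gene_id}\n")


# ---------------------------------------------------------------------------
# plain-text lists, configs and logs
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_json(path: str | Path) -> dict:
    with _open_text(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class JsonlLogger:
    """Append structured events to a JSONL file (one object per line)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=_json_default) + "\n")
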