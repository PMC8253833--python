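"""Shared in-memory containers for the pipeline.

The central object is :class:`ExpressionMatrix`, a genes x cells matrix of
non-negative values carrying a unit tag (FPKM or CPM).  Operations that
are unit-specific (the CPM prefilter, the FPKM expressed-gene rule)
declare the unit they require and refuse a mismatched matrix, because the
two units are not interchangeable in the filtering rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("ctcflow")

VALID_UNITS = ("FPKM", "CPM")


class Site(str, Enum):
    """Vascular sampling sites, ordered along the blood-flow route."""

    HV = "HV"    # hepatic vein (tumor-efferent)
    PA = "PA"    # peripheral artery
    PV = "PV"    # peripheral vein
    PoV = "PoV"  # portal vein (tumor-afferent)
    NA = "NA"

    @classmethod
    def circulation_order(cls) -> list["Site"]:
        return [cls.HV, cls.PA, cls.PV, cls.PoV]


class CellClass(str, Enum):
    CTC = "CTC"
    WBC = "WBC"
    cell_line = "cell_line"
    tumor_bulk = "tumor_bulk"
    peritumor_bulk = "peritumor_bulk"


class UnitMismatchError(ValueError):
    """An operation received a matrix in the wrong expression unit."""


class MetadataMismatchError(ValueError):
    """Cell metadata does not cover the matrix cells (or vice versa)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values with id indices."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"gene id(s) not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"cell id(s) not in matrix: {missing[:5]}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset(
        self,
        genes: Sequence[str] | None = None,
        cells: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        gi = self.gene_index(genes) if genes is not None else np.arange(self.n_genes)
        ci = self.cell_index(cells) if cells is not None else np.arange(self.n_cells)
        return ExpressionMatrix(
            values=self.values[np.ix_(gi, ci)],
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            unit=self.unit,
        )

    def log2p1(self) -> np.ndarray:
        """log2(x + 1) transform of the values (the pipeline's log space)."""
        return np.log2(self.values + 1.0)

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise UnitMismatchError(f"operation requires {unit}, matrix is {self.unit}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata: provenance and QC counters."""

    cell_id: str
    patient_id: str
    site: Site
    cell_class: CellClass
    mapped_reads: int
    detected_genes: int

    def __post_init__(self) -> None:
        if self.mapped_reads < 0 or self.detected_genes < 0:
            raise ValueError("read/gene counts must be non-negative")


def records_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "patient_id": [c.patient_id for c in cells],
            "site": [c.site.value for c in cells],
            "cell_class": [c.cell_class.value for c in cells],
            "mapped_reads": [c.mapped_reads for c in cells],
            "detected_genes": [c.detected_genes for c in cells],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[CellRecord]:
    required = {"cell_id", "patient_id", "site", "cell_class", "mapped_reads", "detected_genes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing column(s): {sorted(missing)}")
    return [
        CellRecord(
            cell_id=str(row.cell_id),
            patient_id=str(row.patient_id),
            site=Site(row.site),
            cell_class=CellClass(row.cell_class),
            mapped_reads=int(row.mapped_reads),
            detected_genes=int(row.detected_genes),
        )
        for row in df.itertuples(index=False)
    ]


def align_metadata(
    matrix: ExpressionMatrix,
    cells: Sequence[CellRecord],
    on_mismatch: str = "error",
) -> list[CellRecord]:
    """Join metadata to the matrix by cell id, in matrix column order.

    ``on_mismatch='error'`` (default) raises on any asymmetric difference;
    ``'intersect'`` warns and keeps the common cells (the matrix itself is
    not modified here; callers subset explicitly).
    """
    by_id = {c.cell_id: c for c in cells}
    matrix_ids = set(matrix.cell_ids)
    meta_ids = set(by_id)
    if matrix_ids != meta_ids:
        only_matrix = sorted(matrix_ids - meta_ids)
        only_meta = sorted(meta_ids - matrix_ids)
        msg = (
            f"metadata/matrix cell mismatch: {len(only_matrix)} matrix-only "
            f"(e.g. {only_matrix[:3]}), {len(only_meta)} metadata-only (e.g. {only_meta[:3]})"
        )
        if on_mismatch == "error":
            raise MetadataMismatchError(msg)
        if on_mismatch == "intersect":
            log.warning("%s; intersecting", msg)
            return [by_id[c] for c in matrix.cell_ids if c in by_id]
        raise ValueError(f"unknown on_mismatch policy: {on_mismatch!r}")
    return [by_id[c] for c in matrix.cell_ids]


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a gene; 0-based half-open (BED convention)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


def sort_loci(loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Genome-sort loci by (chromosome, start) and assign order_index."""
    ordered = sorted(loci, key=lambda l: (l.chromosome, l.start, l.end, l.gene_id))
    return [
        GeneLocus(l.gene_id, l.chromosome, l.start, l.end, order_index=i)
        for i, l in enumerate(ordered)
    ]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional universe for enrichment."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                log.warning(
                    "gene set %s: removed %d duplicate member(s)",
                    name, len(members) - len(unique),
                )
            cleaned[name] = unique
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted_to(self, genes: Iterable[str]) -> "GeneSetCollection":
        present = set(genes)
        return GeneSetCollection(
            sets={n: [g for g in m if g in present] for n, m in self.sets.items()},
            universe=[g for g in (self.universe or []) if g in present] or None,
        )
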