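"""Synthetic CTC cohorts with planted, recoverable structure.

The generator emulates the statistical structure the analysis stages
assume in a multi-patient, four-vascular-site CTC study: a lognormal
baseline expression profile shared by all cells; site-specific expression
programs whose per-cell activation has a controllable cell-to-cell
dispersion (the quantity the heterogeneity statistic measures); a cycling
subpopulation with a boosted G1/S or G2/M signature; genes spiked up in
tumor cells relative to the diploid reference cells; contiguous genomic
segments whose expression is scaled by a copy ratio in tumor cells; and a
transcription-factor/target pair whose log-scale expression is coupled at
a requested Pearson correlation.  Every planted feature is returned as
ground truth so that recovery can be scored exactly.

Randomness is a hierarchy of named substreams derived from a single seed,
so adding or re-ordering one planted component never perturbs the draws
of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    CellClass,
    CellRecord,
    ExpressionMatrix,
    GeneLocus,
    GeneSetCollection,
    Site,
    sort_loci,
)

# Default per-site CTC counts mirror the study design (HV/PA/PV/PoV).
DEFAULT_SITE_CELLS: dict[str, int] = {"HV": 45, "PA": 12, "PV": 40, "PoV": 16}
# Default per-site dispersion of program activation: the arterial
# compartment is the homogeneous one, the venous compartments heterogeneous.
DEFAULT_SITE_DISPERSION: dict[str, float] = {"HV": 1.0, "PA": 0.2, "PV": 1.0, "PoV": 1.0}
# Default planted cycling fractions per site (observed study proportions).
DEFAULT_CYCLING_FRACTION: dict[str, float] = {
    "HV": 0.40, "PA": 0.083, "PV": 0.35, "PoV": 0.563,
}


@dataclass(frozen=True)
class CnvSegmentSpec:
    """A contiguous amplified/deleted block: genes [start_gene, start_gene +
    n_genes) on ``chromosome`` (chromosome-local genome order), expression
    multiplied by ``copy_ratio`` in tumor cells."""

    chromosome: str
    start_gene: int
    n_genes: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")
        if self.n_genes < 1 or self.start_gene < 0:
            raise ValueError("segment must span at least one gene")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.  ``seed`` is mandatory."""

    seed: int
    n_genes: int = 3000
    n_chromosomes: int = 5
    site_cells: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITE_CELLS)
    )
    n_patients: int = 5
    n_reference_cells: int = 8
    # baseline: per-gene log2 mean ~ N(base_log2_mean, gene_mean_sd),
    # per-cell log2 value = gene mean + N(0, noise_sd)
    base_log2_mean: float = 2.0
    gene_mean_sd: float = 1.5
    noise_sd: float = 1.0
    # site-specific programs
    site_program_size: int = 150
    site_program_effect: float = 2.0  # log2 units
    site_dispersion: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_DISPERSION)
    )
    # cell cycle
    cycling_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CYCLING_FRACTION)
    )
    cycle_effect: float = 2.0  # log2 boost on the boosted phase set
    n_g1s_genes: int = 42
    n_g2m_genes: int = 54
    # genes spiked up in tumor cells vs reference cells
    n_de_genes: int = 100
    de_log2fc: float = 2.0
    # copy-number segments (tumor cells only)
    cnv_segments: Sequence[CnvSegmentSpec] = field(
        default_factory=lambda: (CnvSegmentSpec("chr2", 100, 300, 2.0),)
    )
    # TF screen: one TF coupled to the target among n_tfs - 1 nulls
    n_tfs: int = 43
    tf_target_r: float = 0.86
    tf_log2_mean: float = 3.5
    tf_log2_sd: float = 1.2
    # technical dropout: independent Bernoulli zeroing of matrix entries
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, frac in dict(self.cycling_fraction).items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"cycling fraction for {name} outside [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate outside [0, 1]")
        for name, sd in dict(self.site_dispersion).items():
            if sd < 0:
                raise ValueError(f"site dispersion for {name} must be >= 0")
        if not -1.0 <= self.tf_target_r <= 1.0:
            raise ValueError("tf_target_r outside [-1, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticTruth:
    """Ground truth of every planted feature, keyed by the emitted ids."""

    cycling: dict[str, bool]
    cycling_phase: dict[str, str]          # cell -> "G1S" | "G2M" | "none"
    cycling_fraction_planted: dict[str, float]
    de_gene_ids: list[str]
    de_log2fc: dict[str, float]
    cnv_segments: list[dict]               # chromosome, gene_ids, copy_ratio
    tf_ids: list[str]
    coupled_tf: str
    target_gene: str
    tf_target_r_planted: float
    tf_target_r_realized: float            # empirical, pre-dropout
    site_dispersion: dict[str, float]
    program_genes: dict[str, list[str]]    # site -> gene ids
    g1s_genes: list[str]
    g2m_genes: list[str]


def scaled_default_segments(
    n_genes: int, n_chromosomes: int = 5, copy_ratio: float = 2.0
) -> tuple[CnvSegmentSpec, ...]:
    """The default one-segment CNV truth, scaled to fit a smaller genome.

    Mirrors the 3000-gene default (300 genes on chr2 starting a fifth of
    the way in) proportionally.
    """
    per_chrom = int(np.ceil(n_genes / n_chromosomes))
    start = per_chrom // 5
    span = min(max(per_chrom // 2, 1), 300, per_chrom - start)
    return (CnvSegmentSpec("chr2", start, span, copy_ratio),)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named RNG substream derived from one cohort seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _make_loci(n_genes: int, n_chromosomes: int, gene_ids: Sequence[str]) -> list[GeneLocus]:
    per_chrom = int(np.ceil(n_genes / n_chromosomes))
    loci = []
    for i, gid in enumerate(gene_ids):
        chrom = i // per_chrom + 1
        offset = i % per_chrom
        loci.append(
            GeneLocus(gid, f"chr{chrom}", offset * 10_000, offset * 10_000 + 5_000)
        )
    return sort_loci(loci)


def _allocate_roles(spec: SyntheticSpec, loci: list[GeneLocus]) -> dict:
    """Assign disjoint gene-index blocks to each planted feature.

    CNV segments are fixed genomic spans, so every other role is drawn
    from the non-spanned indices; cycle sets and site programs are
    disjoint by construction (overlap would entangle the planted truths).
    """
    per_chrom: dict[str, list[int]] = {}
    for i, l in enumerate(loci):
        per_chrom.setdefault(l.chromosome, []).append(i)
    cnv_idx: set[int] = set()
    segments = []
    for seg in spec.cnv_segments:
        if seg.chromosome not in per_chrom:
            raise ValueError(f"CNV segment on unknown chromosome {seg.chromosome}")
        chrom_genes = per_chrom[seg.chromosome]
        if seg.start_gene + seg.n_genes > len(chrom_genes):
            raise ValueError(
                f"CNV segment exceeds {seg.chromosome} ({len(chrom_genes)} genes)"
            )
        idx = chrom_genes[seg.start_gene : seg.start_gene + seg.n_genes]
        segments.append((seg, list(idx)))
        cnv_idx.update(idx)

    free = [i for i in range(len(loci)) if i not in cnv_idx]
    sites = list(spec.site_cells)
    need = (
        spec.n_g1s_genes + spec.n_g2m_genes
        + spec.site_program_size * len(sites)
        + spec.n_de_genes + spec.n_tfs + 1
    )
    if need > len(free):
        raise ValueError(
            f"{spec.n_genes} genes cannot host all planted features ({need} needed "
            f"outside CNV segments)"
        )
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        block = free[cursor : cursor + k]
        cursor += k
        return block

    roles = {
        "g1s": take(spec.n_g1s_genes),
        "g2m": take(spec.n_g2m_genes),
        "programs": {s: take(spec.site_program_size) for s in sites},
        "de": take(spec.n_de_genes),
        "tfs": take(spec.n_tfs),
        "target": take(1)[0],
        "cnv": segments,
    }
    overlap = set(roles["g1s"]) | set(roles["g2m"])
    for s, idx in roles["programs"].items():
        if overlap & set(idx):
            raise ValueError(f"site program {s} overlaps a cycle gene set")
    return roles


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, list[CellRecord], list[GeneLocus], GeneSetCollection, SyntheticTruth]:
    """Generate one cohort; deterministic given ``spec.seed``."""
    gene_ids = _gene_ids(spec.n_genes)
    loci = _make_loci(spec.n_genes, spec.n_chromosomes, gene_ids)
    # loci are genome-sorted; map locus order back to gene index
    order_of_gene = {l.gene_id: l.order_index for l in loci}
    roles = _allocate_roles(spec, loci)
    # roles are in locus order; translate to row indices of the matrix
    id_at_locus = {l.order_index: l.gene_id for l in loci}
    row_of = {g: i for i, g in enumerate(gene_ids)}

    def rows(locus_idx: Sequence[int]) -> np.ndarray:
        return np.array([row_of[id_at_locus[i]] for i in locus_idx], dtype=int)

    sites = list(spec.site_cells)
    n_tumor = int(sum(spec.site_cells.values()))
    n_cells = n_tumor + spec.n_reference_cells

    # ---- cell bookkeeping -------------------------------------------------
    cell_ids, cell_site, cell_patient, cell_class = [], [], [], []
    for s in sites:
        for j in range(spec.site_cells[s]):
            cell_ids.append(f"CTC_{s}_{j:03d}")
            cell_site.append(s)
            cell_patient.append(f"P{j % spec.n_patients + 1}")
            cell_class.append(CellClass.CTC)
    for j in range(spec.n_reference_cells):
        cell_ids.append(f"WBC_{j:03d}")
        cell_site.append("NA")
        cell_patient.append("P1")
        cell_class.append(CellClass.WBC)
    tumor_mask = np.array([c is CellClass.CTC for c in cell_class])

    # ---- baseline log2 expression ----------------------------------------
    rng_base = substream(spec.seed, "baseline")
    gene_mean = rng_base.normal(spec.base_log2_mean, spec.gene_mean_sd, size=spec.n_genes)
    # differential spikes are planted on expressed genes (baseline log2 mean
    # >= 3): a log2 fold change on a near-silent gene is not meaningful and
    # the +1 pseudocount would compress it below the planted value
    de_rows_pre = rows(roles["de"])
    gene_mean[de_rows_pre] = np.maximum(gene_mean[de_rows_pre], 3.0)
    log2 = gene_mean[:, None] + substream(spec.seed, "noise").normal(
        0.0, spec.noise_sd, size=(spec.n_genes, n_cells)
    )

    # ---- site programs ----------------------------------------------------
    rng_prog = substream(spec.seed, "programs")
    program_genes: dict[str, list[str]] = {}
    for s in sites:
        r = rows(roles["programs"][s])
        program_genes[s] = [gene_ids[i] for i in r]
        members = [i for i, cs in enumerate(cell_site) if cs == s]
        sigma = dict(spec.site_dispersion).get(s, 1.0)
        activation = rng_prog.normal(spec.site_program_effect, sigma, size=len(members))
        for m, a in zip(members, activation):
            log2[r, m] += a

    # ---- cycling subpopulation -------------------------------------------
    rng_cyc = substream(spec.seed, "cycling")
    g1s_rows, g2m_rows = rows(roles["g1s"]), rows(roles["g2m"])
    cycling: dict[str, bool] = {}
    phase: dict[str, str] = {}
    for s in sites:
        members = [i for i, cs in enumerate(cell_site) if cs == s]
        frac = dict(spec.cycling_fraction).get(s, 0.0)
        n_cyc = int(round(frac * len(members)))
        chosen = rng_cyc.choice(members, size=n_cyc, replace=False) if n_cyc else []
        chosen = set(int(c) for c in np.atleast_1d(chosen))
        for m in members:
            cid = cell_ids[m]
            if m in chosen:
                ph = "G1S" if rng_cyc.random() < 0.5 else "G2M"
                log2[g1s_rows if ph == "G1S" else g2m_rows, m] += spec.cycle_effect
                cycling[cid], phase[cid] = True, ph
            else:
                cycling[cid], phase[cid] = False, "none"
    for j in range(n_tumor, n_cells):
        cycling[cell_ids[j]], phase[cell_ids[j]] = False, "none"

    # ---- tumor-upregulated genes (vs reference cells) ---------------------
    de_rows = rows(roles["de"])
    log2[np.ix_(de_rows, np.where(tumor_mask)[0])] += spec.de_log2fc
    de_gene_ids = [gene_ids[i] for i in de_rows]

    # ---- TF/target coupled pair ------------------------------------------
    tf_rows = rows(roles["tfs"])
    tf_ids = [gene_ids[i] for i in tf_rows]
    coupled_row, target_row = tf_rows[0], row_of[id_at_locus[roles["target"]]]
    tumor_cols = np.where(tumor_mask)[0]
    realized = np.nan
    for attempt in range(50):
        rng_tf = substream(spec.seed, f"tf_pair_{attempt}")
        z1 = rng_tf.normal(size=tumor_cols.size)
        z2 = rng_tf.normal(size=tumor_cols.size)
        r = spec.tf_target_r
        t_vals = spec.tf_log2_mean + spec.tf_log2_sd * z1
        f_vals = spec.tf_log2_mean + spec.tf_log2_sd * (
            r * z1 + np.sqrt(max(0.0, 1 - r * r)) * z2
        )
        realized = float(np.corrcoef(t_vals, f_vals)[0, 1])
        if abs(realized - r) <= 0.05:
            break
    log2[target_row, tumor_cols] = t_vals
    log2[coupled_row, tumor_cols] = f_vals

    # ---- assemble FPKM, apply CNV and dropout -----------------------------
    fpkm = np.power(2.0, log2)
    cnv_truth = []
    for seg, locus_idx in roles["cnv"]:
        r = rows(locus_idx)
        fpkm[np.ix_(r, tumor_cols)] *= seg.copy_ratio
        cnv_truth.append(
            {
                "chromosome": seg.chromosome,
                "gene_ids": [gene_ids[i] for i in r],
                "copy_ratio": seg.copy_ratio,
            }
        )
    if spec.dropout_rate > 0:
        keep = substream(spec.seed, "dropout").random(fpkm.shape) >= spec.dropout_rate
        fpkm = fpkm * keep

    matrix = ExpressionMatrix(values=fpkm, gene_ids=gene_ids, cell_ids=cell_ids, unit="FPKM")

    # ---- metadata consistent with the matrix ------------------------------
    rng_meta = substream(spec.seed, "metadata")
    detected = (fpkm > 0).sum(axis=0)
    reads = rng_meta.integers(1_200_000, 8_000_000, size=n_cells)
    cells = [
        CellRecord(
            cell_id=cell_ids[j],
            patient_id=cell_patient[j],
            site=Site(cell_site[j]),
            cell_class=cell_class[j],
            mapped_reads=int(reads[j]),
            detected_genes=int(detected[j]),
        )
        for j in range(n_cells)
    ]

    gene_sets = GeneSetCollection(
        sets={
            "G1S": [gene_ids[i] for i in g1s_rows],
            "G2M": [gene_ids[i] for i in g2m_rows],
            **{f"PROGRAM_{s}": program_genes[s] for s in sites},
        },
        universe=list(gene_ids),
    )
    truth = SyntheticTruth(
        cycling=cycling,
        cycling_phase=phase,
        cycling_fraction_planted={
            s: int(round(dict(spec.cycling_fraction).get(s, 0.0) * spec.site_cells[s]))
            / spec.site_cells[s]
            for s in sites
        },
        de_gene_ids=de_gene_ids,
        de_log2fc={g: spec.de_log2fc for g in de_gene_ids},
        cnv_segments=cnv_truth,
        tf_ids=tf_ids,
        coupled_tf=gene_ids[coupled_row],
        target_gene=gene_ids[target_row],
        tf_target_r_planted=spec.tf_target_r,
        tf_target_r_realized=realized,
        site_dispersion=dict(spec.site_dispersion),
        program_genes=program_genes,
        g1s_genes=[gene_ids[i] for i in g1s_rows],
        g2m_genes=[gene_ids[i] for i in g2m_rows],
    )
    return matrix, cells, loci, gene_sets, truth


def generate_two_group(
    seed: int,
    n_genes: int = 3000,
    n_de: int = 100,
    log2fc: float = 2.0,
    n_a: int = 20,
    n_b: int = 20,
    base_log2_mean: float = 2.0,
    gene_mean_sd: float = 1.5,
    noise_sd: float = 1.0,
    dropout_rate: float = 0.0,
) -> tuple[ExpressionMatrix, list[str], list[str], list[str]]:
    """Two-group design for differential-expression recovery tests.

    The first ``n_de`` genes are shifted up by ``log2fc`` (log2 units) in
    group A; they are planted on expressed baselines (log2 mean >= 3) so
    the planted fold change survives the +1 pseudocount.  Returns
    (matrix, group_a cell ids, group_b cell ids, de gene ids).
    """
    rng = substream(seed, "two_group")
    gene_ids = _gene_ids(n_genes)
    cell_ids = [f"A_{i:03d}" for i in range(n_a)] + [f"B_{i:03d}" for i in range(n_b)]
    gene_mean = rng.normal(base_log2_mean, gene_mean_sd, size=n_genes)
    gene_mean[:n_de] = np.maximum(gene_mean[:n_de], 3.0)
    log2 = gene_mean[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_a + n_b))
    log2[:n_de, :n_a] += log2fc
    fpkm = np.power(2.0, log2)
    if dropout_rate > 0:
        fpkm = fpkm * (rng.random(fpkm.shape) >= dropout_rate)
    matrix = ExpressionMatrix(values=fpkm, gene_ids=gene_ids, cell_ids=cell_ids, unit="FPKM")
    return matrix, cell_ids[:n_a], cell_ids[n_a:], gene_ids[:n_de]


def generate_qc_stress(
    n_cells: int, failing_fraction: float, seed: int, n_genes: int = 4000
) -> tuple[ExpressionMatrix, list[CellRecord]]:
    """Cells of which exactly round(n * fraction) violate a QC rule.

    Failure modes alternate between too few detected genes (< 3000) and
    too few mapped reads (<= 1e6), so both rules are exercised whenever
    two or more cells fail.  Returns the matrix (so the cell filter can
    recompute detected genes) together with consistent metadata.
    """
    if not 0.0 <= failing_fraction <= 1.0:
        raise ValueError("failing_fraction outside [0, 1]")
    if n_genes < 3600:
        raise ValueError("need >= 3600 genes so passing cells can clear the gene rule")
    rng = substream(seed, "qc_stress")
    n_fail = int(round(n_cells * failing_fraction))
    cell_ids = [f"QC_{i:03d}" for i in range(n_cells)]
    gene_ids = _gene_ids(n_genes)
    values = np.power(2.0, rng.normal(2.0, 1.0, size=(n_genes, n_cells)))
    reads = rng.integers(1_500_000, 5_000_000, size=n_cells)
    for i in range(n_cells):
        if i < n_fail:
            mode = "genes" if i % 2 == 0 else "reads"
            if mode == "genes":
                n_detected = int(rng.integers(1000, 2999))
            else:
                n_detected = int(rng.integers(3600, n_genes))
                reads[i] = int(rng.integers(100_000, 1_000_000))
        else:
            n_detected = int(rng.integers(3600, n_genes))
        silent = rng.choice(n_genes, size=n_genes - n_detected, replace=False)
        values[silent, i] = 0.0
    matrix = ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, unit="FPKM")
    detected = (values > 0).sum(axis=0)
    cells = [
        CellRecord(
            cell_id=cell_ids[i],
            patient_id="P1",
            site=Site.NA,
            cell_class=CellClass.CTC,
            mapped_reads=int(reads[i]),
            detected_genes=int(detected[i]),
        )
        for i in range(n_cells)
    ]
    return matrix, cells
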