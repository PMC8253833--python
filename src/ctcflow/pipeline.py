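"""End-to-end orchestration of the analysis stages.

A run is driven by a single JSON config (seed, input paths or a
simulation block, per-stage parameters) and writes every stage output
under one run directory together with a resolved-config snapshot and a
manifest recording file, stage and SHA-256 checksum, so identical
config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import cell_cycle, cnv, heterogeneity, io, markers, qc, tf_screen
from .datamodel import CellClass, ExpressionMatrix
from .simulate import CnvSegmentSpec, SyntheticSpec, generate_cohort

log = logging.getLogger("ctcflow")


class ConfigError(ValueError):
    """The run config is missing a field or points at a missing file."""


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    inputs: dict[str, str] | None = None      # matrix, cells, loci, gmt, tf_list, target
    simulate: dict[str, Any] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config field missing: seed")
        if "output_dir" not in raw:
            raise ConfigError("config field missing: output_dir")
        known = {"seed", "output_dir", "inputs", "simulate", "params", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw["output_dir"]),
            inputs=raw.get("inputs"),
            simulate=raw.get("simulate", {}),
            params=raw.get("params", {}),
            log_level=raw.get("log_level", "INFO"),
        )

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "inputs": self.inputs,
            "simulate": self.simulate,
            "params": self.params,
            "log_level": self.log_level,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_spec(seed: int, overrides: dict[str, Any]) -> SyntheticSpec:
    overrides = dict(overrides)
    if "cnv_segments" in overrides:
        overrides["cnv_segments"] = tuple(
            CnvSegmentSpec(**seg) if isinstance(seg, dict) else seg
            for seg in overrides["cnv_segments"]
        )
    elif "n_genes" in overrides:
        # rescale the default planted segment to the requested genome size
        from .simulate import scaled_default_segments

        overrides["cnv_segments"] = scaled_default_segments(
            overrides["n_genes"], overrides.get("n_chromosomes", 5)
        )
    return SyntheticSpec(seed=seed, **overrides)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load → qc → het → cycle → markers → cnv → tfscreen.

    Returns the manifest dict (also written to manifest.json).  Raises
    ConfigError on missing inputs before any stage output is written.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    logger = io.JsonlLogger(outdir / "run_log.jsonl")
    manifest: list[dict] = []

    def emit(stage: str, name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append({"file": name, "stage": stage, "sha256": _sha256(path)})
        logger.event(stage, wrote=name)

    # ---- inputs -----------------------------------------------------------
    truth = None
    tf_list: list[str] | None = None
    target: str | None = None
    if config.inputs:
        required = ["matrix", "cells", "loci", "gmt"]
        for key in required:
            if key not in config.inputs:
                raise ConfigError(f"inputs field missing: {key}")
            if not Path(config.inputs[key]).exists():
                raise ConfigError(f"input file not found: {config.inputs[key]}")
        matrix = io.read_expression_tsv(config.inputs["matrix"], unit="FPKM")
        cells = io.read_cells_csv(config.inputs["cells"])
        loci = io.read_loci(config.inputs["loci"])
        gene_sets = io.read_gmt(config.inputs["gmt"])
        if "tf_list" in config.inputs:
            if not Path(config.inputs["tf_list"]).exists():
                raise ConfigError(f"input file not found: {config.inputs['tf_list']}")
            tf_list = io.read_gene_list(config.inputs["tf_list"])
            target = config.inputs.get("target")
            if target is None:
                raise ConfigError("inputs field missing: target (required with tf_list)")
    else:
        spec = build_spec(config.seed, config.simulate)
        matrix, cells, loci, gene_sets, truth = generate_cohort(spec)
        tf_list, target = truth.tf_ids, truth.target_gene
        emit("simulate", "matrix.tsv", lambda p: io.write_expression_tsv(matrix, p))
        emit("simulate", "cells.csv", lambda p: io.write_cells_csv(cells, p))
        emit("simulate", "loci.bed", lambda p: io.write_loci(loci, p))
        emit("simulate", "gene_sets.gmt", lambda p: io.write_gmt(gene_sets, p))
        emit("simulate", "truth.json", lambda p: io.write_json(_truth_dict(truth), p))

    emit("config", "config.resolved.json",
         lambda p: io.write_json(config.resolved(), p))

    # ---- qc ---------------------------------------------------------------
    qc_params = config.params.get("qc", {})
    report = qc.filter_cells(matrix, cells, **qc_params)
    emit("qc", "qc_flags.csv", lambda p: report.flags.to_csv(p, index=False))
    emit("qc", "qc_summary.json", lambda p: io.write_json(report.summary(), p))
    passing = set(report.passing_cells)
    if not passing:
        raise ValueError(
            "no cells pass QC; check min_genes/min_reads against the cohort "
            f"(matrix has {matrix.n_genes} genes)"
        )
    cells = [c for c in cells if c.cell_id in passing]
    matrix = matrix.subset(cells=[c.cell_id for c in cells])

    ctc_ids = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]
    wbc_ids = [c.cell_id for c in cells if c.cell_class is CellClass.WBC]

    # ---- heterogeneity ----------------------------------------------------
    het_params = config.params.get("het", {})
    het = heterogeneity.site_heterogeneity(matrix, cells, **het_params)
    emit("het", "heterogeneity_pairs.csv", lambda p: _pairs_frame(het).to_csv(p, index=False))
    emit("het", "heterogeneity_summary.json",
         lambda p: io.write_json({**het.summary(),
                                  "comparisons": het.comparisons.to_dict("records")}, p))

    # ---- cell cycle -------------------------------------------------------
    cyc_params = config.params.get("cycle", {})
    g1s = gene_sets["G1S"] if "G1S" in gene_sets else None
    g2m = gene_sets["G2M"] if "G2M" in gene_sets else None
    scores = cell_cycle.cycle_scores(matrix.subset(cells=ctc_ids),
                                     g1s_set=g1s, g2m_set=g2m, cells=cells)
    scores = cell_cycle.classify_cycling(scores, **cyc_params)
    emit("cycle", "cycle_scores.csv",
         lambda p: cell_cycle.scores_to_frame(scores).to_csv(p, index=False))
    emit("cycle", "cycle_summary.json",
         lambda p: io.write_json({"site_percent_cycling":
                                  cell_cycle.site_proportions(scores)}, p))

    # ---- markers (tumor cells vs reference cells) -------------------------
    if len(ctc_ids) >= 2 and len(wbc_ids) >= 2:
        mk_params = config.params.get("markers", {})
        mtable = markers.run_cascade(matrix, ctc_ids, wbc_ids,
                                     contrast="CTC_vs_WBC", **mk_params)
        emit("markers", "markers.csv", lambda p: mtable.table.to_csv(p, index=False))
        emit("markers", "markers_summary.json",
             lambda p: io.write_json(mtable.summary(), p))
        final_genes = mtable.at_stage("final")
        if final_genes:
            enr = markers.enrich(final_genes, gene_sets,
                                 universe=gene_sets.universe or matrix.gene_ids)
            emit("markers", "enrichment.csv", lambda p: enr.to_csv(p, index=False))
    else:
        mtable = None
        log.warning("markers stage skipped: need >= 2 tumor and >= 2 reference cells")

    # ---- CNV --------------------------------------------------------------
    if wbc_ids:
        cnv_params = config.params.get("cnv", {})
        profiles = cnv.infer_cnv(matrix, loci, reference_cells=wbc_ids, **cnv_params)
        emit("cnv", "cnv_profiles.csv",
             lambda p: cnv.profiles_to_frame(profiles).to_csv(p, index=False,
                                                              float_format="%.6g"))
    else:
        log.warning("cnv stage skipped: no reference cells")

    # ---- TF screen --------------------------------------------------------
    if tf_list and target:
        tf_params = config.params.get("tfscreen", {})
        screen = tf_screen.screen_tfs(matrix, tf_list, target, cells=ctc_ids, **tf_params)
        emit("tfscreen", "tf_screen.csv", lambda p: screen.table.to_csv(p, index=False))
        emit("tfscreen", "tf_screen_summary.json",
             lambda p: io.write_json(screen.summary(), p))
    else:
        log.warning("tfscreen stage skipped: no TF list/target given")

    manifest_obj = {"seed": config.seed, "files": manifest}
    io.write_json(manifest_obj, outdir / "manifest.json")
    return manifest_obj


def _pairs_frame(het_report):
    import pandas as pd

    rows = []
    for site, rs in het_report.pair_correlations.items():
        for r in rs:
            rows.append({"site": site, "r": float(r)})
    return pd.DataFrame(rows)


def _truth_dict(truth) -> dict:
    return {
        "cycling": truth.cycling,
        "cycling_phase": truth.cycling_phase,
        "de_gene_ids": truth.de_gene_ids,
        "cnv_segments": truth.cnv_segments,
        "tf_ids": truth.tf_ids,
        "coupled_tf": truth.coupled_tf,
        "target_gene": truth.target_gene,
        "tf_target_r_planted": truth.tf_target_r_planted,
        "tf_target_r_realized": truth.tf_target_r_realized,
        "site_dispersion": truth.site_dispersion,
        "program_genes": truth.program_genes,
        "g1s_genes": truth.g1s_genes,
        "g2m_genes": truth.g2m_genes,
    }
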