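# ctcflow

Analysis toolkit for single-cell RNA-seq of **circulating tumor cells
(CTCs) sampled at multiple vascular sites**.  In hepatocellular-carcinoma
studies, single CTCs can be drawn from four points along the blood-flow
route — hepatic vein (HV), peripheral artery (PA), peripheral vein (PV)
and portal vein (PoV) — and their transcriptomes change as they travel.
`ctcflow` implements the bespoke computational procedures such a study
needs, as a tested, reusable pipeline:

- **QC filtering** — cells kept only with ≥ 3000 detected genes
  (FPKM > 0) and > 1 M uniquely mapped reads; expressed-gene filter
  (FPKM > 1 in > 10 % of cells).
- **Heterogeneity** — over the top-2000 genes by variance of
  log2(FPKM + 1), the Pearson correlation *r* of every unordered pair of
  CTCs within a site; a site's heterogeneity is 1 minus how concordant
  its cells are, summarized by mean *r* (lower mean *r* ⇔ higher
  heterogeneity), with site-vs-site two-sided Wilcoxon rank-sum (or
  Welch *t*) comparisons.
- **Cell-cycle state** — relative expression
  *E*ᵢⱼ = log2(FPKMᵢⱼ + 1) − meanⱼ log2(FPKMᵢⱼ + 1), averaged over a
  42-gene G1/S and a 54-gene G2/M signature per cell; cells are
  classified cycling/noncycling by a 2-cluster hierarchical cut on
  max(G1/S, G2/M) or by a plain threshold.
- **Marker cascade** — staged differential expression: CPM prefilter →
  per-gene Wilcoxon rank-sum on log2(x + 1) with |log2FC| > 1, *P* < 0.05
  and BH FDR < 0.05 (*initial*) → mean FPKM fold change > 1 (log2) toward
  the up-group and expressed in ≥ 90 % of up-group cells (*potential*) →
  confirmatory rank-sum *P* < 0.05 (*final* markers); hypergeometric
  gene-set enrichment of the result with BH correction.
- **Expression CNV** — per-cell log2 expression centered on diploid
  reference cells (e.g. WBCs), smoothed by a 201-gene moving average
  along genome order within chromosomes, median-recentred, and denoised
  with a logistic weight (midpoint 2 reference-SDs).
- **TF screen** — rank transcription factors by Pearson correlation with
  a target gene (e.g. the chemokine *CCL5*) across CTCs, with t-based
  p-values and BH correction.
- **Synthetic cohorts** — a generator that plants all of the above
  (site programs with controllable cell-to-cell dispersion, cycling
  subpopulations, DE spikes, CNV segments, a TF–target pair coupled at a
  requested *r*) with full ground truth, so every stage is testable
  without access to restricted patient data.

## Worked example

```python
from ctcflow import SyntheticSpec, generate_cohort
from ctcflow import heterogeneity as het, cell_cycle as cc, tf_screen as tfs
from ctcflow.datamodel import CellClass

matrix, cells, loci, sets, truth = generate_cohort(SyntheticSpec(seed=1))
ctc = [c.cell_id for c in cells if c.cell_class is CellClass.CTC]

rep = het.site_heterogeneity(matrix, cells)
print({k: round(v, 3) for k, v in rep.mean_r.items()})
# {'HV': 0.628, 'PA': 0.656, 'PV': 0.621, 'PoV': 0.626}

scores = cc.classify_cycling(
    cc.cycle_scores(matrix.subset(cells=ctc), sets["G1S"], sets["G2M"], cells=cells))
print(cc.site_proportions(scores))
# {'HV': 40.0, 'PA': 8.3, 'PV': 35.0, 'PoV': 56.2}

screen = tfs.screen_tfs(matrix, truth.tf_ids, truth.target_gene, cells=ctc)
print(screen.summary())
# {'target': 'G1139', 'n_tfs': 43, 'n_positive': 3, 'top_tf': 'G1096',
#  'top_r': 0.854, 'top_p': 2.86e-33, 'restricted_to_stage': None}
```

The default cohort plants low program dispersion in PA (σ = 0.2) and
high in the venous sites (σ = 1.0), so PA shows the highest mean
pairwise *r* (least heterogeneity); the planted per-site cycling
fractions (40 %, 8.3 %, 35 %, 56.3 %) are recovered by the classifier;
and the one TF coupled to the target at *r* = 0.86 tops the screen with
an estimate close to the planted value.

The same stages are available from the shell:

```bash
ctcflow simulate --seed 1 --outdir cohort/
ctcflow het --matrix cohort/matrix.tsv --cells cohort/cells.csv --out het/
ctcflow run --config run_config.json     # full pipeline with manifest
```

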