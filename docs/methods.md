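# Methods

This note documents the statistical procedures `ctcflow` implements, the
choices made where a convention was genuinely open, the synthetic-data
model used to validate them, and what the validation does and does not
show about real data.

## Statistical primitives

**Wilcoxon rank-sum.**  All group comparisons use the unpaired two-sided
rank-sum (Mann–Whitney) test — the design compares independent cell
groups, so the *unpaired* form is the correct one even where "signed
rank" is colloquially used for this kind of comparison.  For combined
sample sizes ≤ 12 the p-value is exact: every assignment of the pooled
observations to the two groups is enumerated and
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))) for the observed rank sum *w*,
with ties handled by midranks (the enumeration is then still exact).
Larger samples use the normal approximation with the midrank tie
correction and a 0.5 continuity correction.  The switchover size is a
parameter.

**t tests.**  Welch's unequal-variance *t* is the default — the site
groups are small and unbalanced (e.g. 45 vs 12 cells), where the pooled
assumption is fragile — with the classical pooled form available.  Two
zero-variance groups with equal means return p = 1 by convention;
zero variance with unequal means is an error rather than p = 0, because
it almost always indicates degenerate input.

**Multiple testing.**  Benjamini–Hochberg step-up, implemented directly
from the definition q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j (clipped to 1) and
cross-checked in the test suite against statsmodels.

**Gene-set overlap.**  Upper-tail hypergeometric P(X ≥ k) for an overlap
of *k* between a query of size *n* and a set of size *K* in a universe
of *N* genes, BH-corrected across sets.  This is an overlap test on
discrete gene lists, not a rank-based enrichment statistic.

## Quality control

Cells are kept when they express ≥ 3000 genes (value > 0) **and** carry
more than 10⁶ uniquely mapped reads.  The boundary semantics are literal
and deliberate: 2999 genes fails, 3000 passes; exactly 10⁶ reads fails,
10⁶ + 1 passes ("1 M" is read as 10⁶).  Detected-gene counts are always
recomputed from the matrix; metadata counts are reported but never
trusted when a matrix is available (a discrepancy is logged).  The
expressed-gene filter keeps genes with FPKM > 1 in > 10 % of the chosen
cells, both inequalities strict.  These conventions are documented
because off-by-one behaviour differs silently between tools.

## Heterogeneity statistic

Gene selection: top 2000 genes by variance of log2(FPKM + 1) across the
analysed cells, computed on the pooled cell set by default (a per-patient
selection mode exists for single-patient analyses); ties break by
ascending gene id so the selection is deterministic.  Within each
vascular site, Pearson *r* is computed for **every unordered pair** of
CTCs over the selected genes — C(n_site, 2) values per site.  A pair
whose profile is constant over the selected genes has no defined
correlation; it is dropped and counted, never imputed.  Site
distributions are compared with the two-sided rank-sum test by default
(Welch's *t* optional; both can be reported).

Two caveats are intrinsic to this statistic and documented rather than
hidden: (i) pairs sharing a cell are not independent, but are treated as
such by the tests, as is conventional for this statistic; (ii) in a
multi-patient pooled analysis a patient effect can masquerade as site
homogeneity — `within_patient_pairs=True` restricts pairs to cells of
the same patient for that situation.  The default takes all within-site
pairs, which matches the statistic's definition and is exactly right for
the synthetic cohorts, which have no patient effect by construction.

## Cell-cycle scoring and classification

Relative expression of gene *i* in cell *j* is
E[i, j] = log2(x[i, j] + 1) − mean over cells of log2(x[i, ·] + 1), so
every gene's relative expression sums to zero across the scored cells.
The centering population is the cell set passed in (typically all CTCs
pooled); per-site centering is obtained by subsetting first.  A cell's
G1/S and G2/M scores are the means of E over the 42-gene replication and
54-gene mitosis signatures shipped with the package (a standard
single-cell-derived signature; any GMT with sets named `G1S`/`G2M`
substitutes).

Classification offers two auditable modes.  `threshold` calls a cell
cycling iff max(G1/S, G2/M) ≥ 1 (log2 units; parameter).  `hclust2`
(default) clusters cells by Ward/Euclidean on the combined activity
max(G1/S, G2/M) and cuts at two clusters, calling the higher-mean
cluster cycling.  The cut is taken on the 1-D activity axis rather than
the raw 2-D score plane: the plane is three-lobed (noncycling, G1/S-high,
G2/M-high) and a two-cluster cut there tends to split cycling cells by
phase — on planted truth this costs roughly half the sensitivity —
whereas "cycling" is by definition high activity in *either* phase.
Neither mode claims to reconstruct any particular dendrogram-cut rule;
both are declared choices.

## Marker cascade

Stages are strictly nested (final ⊆ potential ⊆ initial ⊆ tested) and
each gene carries a single ordered stage label:

1. *Prefilter*: genes with CPM < 1 in more than 2 samples are removed.
   The literal count "2" is scale-dependent (sensible for ~14 bulk
   samples, harsh for >100 single cells) and is therefore a parameter.
2. *Initial*: per-gene two-sided rank-sum on log2(x + 1);
   log2FC = difference of group means of log2(x + 1) (mean-of-logs, not
   log-of-mean-ratio; pseudocount 1); requires |log2FC| > 1, P < 0.05
   and BH FDR < 0.05 over the tested genes.
3. *Potential*: group-mean log2-FPKM fold change > 1 toward the up-group
   and expressed (FPKM > 1) in ≥ 90 % of up-group cells.
4. *Final*: confirmatory rank-sum P < 0.05.

The single core test is the rank-sum test throughout; a
negative-binomial count model is deliberately not implemented (the
pipeline consumes FPKM-like continuous values), and the cascade's test
is pluggable should one be wanted.

## Expression-based CNV

Steps, in order: (1) keep genes with mean raw expression across all
cells ≥ 1 (the "cutoff" is a gene-retention floor on mean FPKM, the
conventional meaning; configurable); (2) per gene,
signal = log2(x + 1) − mean over reference cells; (3) centered moving
average of 201 genes along genome order, **within** chromosomes, with
edge windows truncated — smoothing never crosses a chromosome boundary
and chromosomes with < 3 retained genes are dropped; (4) per-cell median
re-centering, a guard against library-size artifacts; (5) logistic
denoising: each value *v* is scaled by
w = 1/(1 + exp(−s·(|v|/σ_ref − m))) with midpoint m = 2 (in units of
σ_ref, the SD of the reference cells' smoothed signal) and steepness
s = 4.  The steepness is not dictated by any convention; it is an
explicit parameter, and the attenuation is monotone in |v| with values
near zero attenuated to ≈ 0.  Coordinates are 0-based half-open
(BED convention).

A caveat the validation makes visible: genuinely differential genes
(site programs, tumor-upregulated genes) produce real smoothed signal
against a normal-cell reference that is not copy number.  This is a
property of all expression-based CNV inference; the boundary-localization
test therefore uses a cohort whose only tumor/reference difference is
the planted segment.

## TF screen

Pearson *r* of each catalogued TF with the target gene on log2(x + 1)
across the chosen cells; two-sided p from the t transform of *r* (an
exact permutation p is available for n ≤ 10); BH across TFs; ranked by
descending *r* with deterministic tie-breaks.  The TF catalogue is an
input, never a default, and an optional restriction to TFs at a chosen
marker-cascade stage emulates "TFs upregulated in the tumor
compartment".  Enhancer-annotation whitelists are user-supplied files,
not an embedded database.

## Synthetic cohorts

The generator emulates a four-site, multi-patient CTC cohort in FPKM
units.  Defaults (all overridable) are the study conditions used
throughout the tests:

- **Geometry**: 3000 genes on 5 chromosomes; 45/12/40/16 CTCs in
  HV/PA/PV/PoV; 5 patients assigned round-robin; 8 reference WBCs.
- **Baseline**: per-gene log2 mean ~ N(2, 1.5²); per-cell log2 value =
  gene mean + N(0, 1).  Lognormal expression matches the skew of FPKM
  data; counts are deliberately not modelled.
- **Site programs**: 150 genes per site, per-cell activation
  ~ N(2, σ_site²) log2 units with σ = 0.2 in PA and 1.0 elsewhere — the
  arterial compartment is the homogeneous one, which is the structure
  the heterogeneity statistic is meant to detect.
- **Cycling**: planted per-site fractions 40 %/8.3 %/35 %/56.3 %
  (exact counts, not Bernoulli, so planted proportions are recoverable);
  each cycling cell gets +2 log2 on one phase signature.
- **Tumor-upregulated genes**: 100 genes at +2 log2 in all CTCs vs the
  reference cells, planted on expressed baselines (log2 mean ≥ 3):
  a fold change planted on a near-silent gene is not meaningful and the
  +1 pseudocount would compress it below its nominal value.
- **CNV**: one 300-gene segment on chr2 at copy ratio 2.0, multiplying
  FPKM in tumor cells only.
- **TF pair**: 43 TF genes of which one is coupled to the target through
  a bivariate normal in log2 space at r = 0.86; the draw is repeated on
  fresh substreams until the realized correlation is within ±0.05 of the
  request (a calibration check, not a fit).
- **Dropout**: independent Bernoulli zeroing at rate 0 by default.  The
  cohorts emulate post-QC full-length (SMART-seq2-style) FPKM matrices,
  where cells are required to express thousands of genes and technical
  zeros among expressed genes are rare; moreover, because dropout here
  is expression-independent, zeroing log-scale values of 3–5 units is a
  far harsher perturbation than real, expression-dependent dropout, and
  even a 5 % rate visibly attenuates planted log-space correlations.
  The knob exists for stress-testing and is exercised at 0.1–0.3 in the
  test suite.

Randomness is a hierarchy of named substreams hashed from one seed, so
adding a planted component never perturbs the draws of another, and the
same spec + seed reproduces the cohort byte-for-byte.

**What passing these tests shows — and does not.**  Recovery on these
cohorts demonstrates that each implementation detects the structure it
is specified to detect at realistic effect sizes and sample counts.  It
does not demonstrate robustness to features the generator omits:
expression-dependent dropout, gene–gene correlation beyond the planted
programs, patient-specific baselines, gene-length/GC effects, doublets,
or ambient contamination.  The headline numbers from the original
patient cohorts (e.g. absolute DEG counts) are functions of restricted
data and are not reproduced here.

## Problem sizes in the validation runs

The acceptance checks use 100 cohorts for the heterogeneity ordering and
the TF screen, 20 for cycling recovery, 5 two-group designs (3000 genes,
20 vs 20 cells) for the marker cascade, and one cohort per copy ratio
{1.5, 2, 3} for CNV; these sizes give stable Monte-Carlo estimates of
the recovery rates while keeping a full validation run around a minute
on one core.
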