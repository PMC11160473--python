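# Methods

This note documents the models, defaults, and design choices behind
`antseq`, and what the synthetic study conditions do and do not establish
about real data.

## Single-nucleus pipeline

### Cell and gene filtering

Two-stage per-cell QC on raw counts, all bounds strict inequalities:

| bound | lenient (stage 1) | stringent (stage 2, additional) |
|---|---|---|
| detected genes (nonzero counts) | ≥ 750 | ≤ 2,750 |
| UMIs | ≤ 12,500 | ≤ 9,500 |
| mitochondrial reads | ≤ 2.5% | ≤ 1.25% |

"Detected gene" means a nonzero count; no other definition is used.
Mitochondrial genes are identified by annotation class (`mito`), or by an ID
prefix list on real data. Named rRNA genes can be dropped with
`remove_rrna_genes`. The removal log records every rule each removed cell
violated. The full pipeline applies the stringent stage, mirroring the
final configuration of the protocol it implements.

### Normalization, HVGs, latent space

Counts are depth-normalized to 10,000 per cell and log1p-transformed
(natural log). Highly variable genes are selected per batch (library) as
the top `n_hvg` (default 2,000) by standardized variance — gene variance of
log-normalized values divided by a rolling-median (window 151) variance
trend over mean-ordered genes — with per-batch ranks combined by median and
ties broken by gene ID; batches under 50 cells are excluded with a warning.
This is a deliberate stand-in for the seurat_v3 trend fit: the downstream
consumer is only a ranking.

The latent space is PCA (genes centered and unit-scaled; deterministic sign
convention: the largest-magnitude loading of each component is positive).
`n_pcs` defaults to 30; `pca_embed` also reports an elbow suggestion (first
component whose explained-variance drop falls below 5% of the previous
drop) for data-driven choices. A variational batch-correction model is
intentionally *not* used: every downstream statistic depends only on the
kNN graph, and a deterministic latent space keeps runs exactly
reproducible. Batch effects are instead handled at HVG level; this is a
documented deviation from the protocol this package re-implements, which
used a scVI latent space.

The kNN graph is exact (brute force, Euclidean), `n_neighbors` = 15,
symmetrized by union with unit edge weights. Clustering is Leiden on the
RB-configuration quality function at resolution 5 (seeded, hence
deterministic). UMAP is not computed — it served only visualization in the
source protocol.

### Receptor calling

For each neuronal cell and each receptor-class gene (tuning Or, orco,
tuning Ir, irco, Gr, plus Rh50 and nompC), the gene's log-normalized values
over {focal cell} ∪ {its `n_neighbors` graph neighbors} are compared to the
values over one fixed background of `background_size` = 100 WT nonneuronal
cells, drawn uniformly once per run. The test is one-sided Mann–Whitney
(neighborhood greater); `alpha` = 0.05 on the raw p-value labels the cell
expressing. Choices worth stating:

- The focal cell is included in its own neighborhood (the neighborhood
  definition is otherwise underdetermined); neighborhoods are
  genotype-agnostic.
- One background for all genes and cells keeps calls comparable across
  genes.
- For pooled sizes n+m ≤ 12 the p-value is exact by enumeration of all
  C(n+m, n) group assignments, computing U with midrank tie handling —
  tied data are handled without approximation. Larger samples (the
  pipeline's 16-vs-100 case) use the tie-corrected normal approximation
  with continuity correction. Columns with no variation give p = 1.
- No multiple-testing correction across genes or cells; this reproduces
  the protocol faithfully and is anti-conservative by construction. The
  practical false-call rate is far below alpha because most receptor
  columns are all-zero over both neighborhood and background.
- Rank tests are invariant to monotone transforms, so testing log-CP10k
  equals testing CP10k.
- Nonneuronal cells get all-false call rows; they are classified at
  cluster level.

### Cluster gating and categories

A cluster expresses a marker when ≥ 25% of its cells have a nonzero count
AND its mean normalized expression exceeds the dataset mean for that gene
(the source protocol prints no threshold; this one is robust to dropout at
the scales used here). Neuronal clusters must express all four neuron
markers simultaneously; remaining clusters are gated glia → muscle →
epithelium → support by their single markers, else "other nonneuronal".

Neurons are then assigned a receptor-combination category by a
first-match-wins rule table over seven boolean predicates. The default
table is a reconstruction (the authoritative per-category predicate list is
not in the public text) and is data, not code — it can be edited or
replaced. Ordering choices that matter: the orco+Ir+irco rule precedes the
OrX rules (so the +OrX variant folds into it), and the mechanosensory and
ammonia rules require absence of tuning-Or calls but not of orco — a rare
contaminated-neighborhood orco false call should not eject a nompC or Rh50
cell from its class.

### Survival table

Per category: WT/mutant counts, within-genotype fractions (summing to 1 per
genotype), the mutant/WT count ratio, a depletion odds ratio with
Haldane–Anscombe 0.5 correction when any 2×2 cell is zero, and a two-sided
Fisher exact p. The odds ratio and p are extensions (the protocol reports
proportions without a test) and are labeled as such. The count ratio is the
cleanest survival readout under the generator's design, where both
genotypes start from equal-size pre-ablation cohorts; fully surviving
categories have expected ratio 1, ablated ones ~0. Note that
*within-genotype fractions* of surviving categories necessarily inflate in
the mutant (the denominator shrinks when other cells die): a fully
surviving class at WT fraction f appears at fraction ≈ f / (surviving mass)
among mutant nuclei. Interpreting survival therefore uses the count ratio,
not the fraction ratio.

## Bulk pipeline

Median-of-ratios size factors follow the DESeq2 estimator exactly:
reference = per-gene geometric mean over samples (genes with any zero
excluded), factor = per-sample median of count/reference. Two exact
equivariances hold and are tested: global scaling leaves factors unchanged
(the reference rescales too), and scaling one sample by c scales its factor
*relative to every other sample* by c. FPKM = count × 10⁹ / (length ×
mapped total).

The variance-stabilizing transform is approximated by log1p of normalized
counts; the only consumer is a loadings ranking, which is robust to the
exact transform. Stage-biased gene sets take the `loading_set_size`
(default 750) genes with the largest positive PC1 loading (early), most
negative PC1 (late), and most negative PC2 (intermediate), from a PCA over
samples with genes centered. PC signs are arbitrary, so PC1 is oriented
against stage rank (early samples positive) and PC2 against a D15
indicator. Sets are disjoint with priority early > late > intermediate:
both stage-extreme sets live on PC1 and claim their genes first, so a
low-variance PC2 cannot capture stage-axis genes (degenerate low-rank
inputs otherwise misassign). Each set is restricted to loadings of the
correct sign and truncated with a warning when fewer qualify.

## Retained-Or screening

Fold changes are computed on each platform's natural abundance scale —
CP10k means over *all* cells of a genotype (single-nucleus) and FPKM means
over samples (bulk) — and log2-transformed; a platform reports a gene only
if its mean is nonzero in both genotypes there. The retention cutoffs
(default −1/−1 log2) stand in for an unprinted "arbitrary cutoff" and are
prominent config values. One compositional fact matters when reading the
single-nucleus axis: after ablation removes ~62% of mutant cells, every
surviving population is ~2.7× enriched among mutant nuclei, so genes hosted
by surviving (e.g. nonneuronal) cells sit near +1.4 rather than 0. The
cutoff at −1 is agnostic to this shift. Leaky-regulation scoring uses plain
nonzero-mask Jaccard over nonneuronal cells (not Mann–Whitney calls —
nonneuronal cells are excluded from the calling procedure by construction)
and midpoint-to-midpoint genomic distance, strand ignored.

## ID transfer

Tier 1: reciprocal best hits on bit-score; ties or asymmetry block a match.
Tier 2: between consecutive non-crossing anchors (crossing anchors are
demoted by longest-increasing-subsequence and the fill recomputed), the
unassigned genes of the gap are aligned by Needleman–Wunsch with pairwise
score = percent identity (missing pairs 0) and a flat gap penalty (default
40 identity points); aligned pairs need `min_identity` (default 60).
Identity, not bit-score, drives this tier: truncated gene models deflate
alignment scores roughly in proportion to lost length while identity over
the aligned region is preserved. Unassigned genes whose top bit-score hit
already belongs to another query are flagged `unmatched_collapsed` (two old
genes, one new locus); the rest `unmatched_novel`. The alignment
formulation is a formalization of manual synteny-guided curation; the gap
penalty and identity floor have no published counterparts and are config
values.

## Synthetic study conditions

The generator is the package's ground truth and encodes the study
conditions; its defaults are fixed, not tuning knobs.

**Single-nucleus** (desk scale): 1,200 genes — 300 tuning Or (10 of them
"retained", each beside a non-Or leak-partner gene on its own scaffold),
orco, 4 ircos (Ir8a, Ir25a.1, Ir25a.2, Ir76b), 20 tuning Ir, 10 Gr, Rh50,
nompC, 8 class markers, 30 mitochondrial, the rest housekeeping/background.
2,000 cells per genotype are drawn pre-ablation from ~30 cell programs:
twelve OrX+orco types plus OrX+orco+Gr, OrX+orco+irco, orco-only (total
weight 0.625, mutant survival 0.005 — "almost absent", not exactly zero, so
complete loss remains distinguishable from absence of evidence),
orco+Ir+irco (0.021), Ir+irco, Gr-only, nompC and Rh50 types (surviving
neuron mass 0.045 in total), and glia/muscle/epithelium/support/other
nonneuronal (0.33). This puts WT neurons at 67% and, after thinning,
mutant neurons at ~12–13% of the sequenced mutant dataset. Counts are
negative binomial with mean μ and size θ = 10 (variance μ + μ²/θ); receptor
program means are 3 expected UMI at unit depth, housekeeping 3.5, cell
depths log-normal (σ = 0.10), one WT library carries a per-gene log-normal
batch factor (σ = 0.08), and mitochondrial genes are tuned to ~0.6% of
reads. Every program additionally modulates a random 40+40-gene identity
module (×4.0 / ×0.3) of housekeeping genes: real cell types differ in broad
transcriptional programs, not only in their 1–4 receptor genes, and without
that structure no embedding could recover them (the receptor signal alone
sits below the noise floor of a 1,200-gene PCA). Module membership is part
of the program definitions (fixed internal seed), independent of the
simulation seed.

Deliberately *not* simulated: ambient RNA (baseline expression of
unexpressed genes is 0 by default; the parameter exists and is tested),
doublets, spliced/unspliced structure. Consequently the calling procedure's
practical specificity here is higher than on real data, where ambient
receptor counts exist; the type-I calibration test bounds the per-gene
rate, not the ambient regime.

**Bulk**: stages D10/D15/D20/D25 × WT/mutant × 3 replicates; gene base
abundances log-normal (log-mean 5, σ = 1); trajectory classes: 150-gene
early (peak D10), intermediate (peak D15) and late (plateau D20–25)
programs, "Or-like" for all ORN-hosted Ors (WT rise to plateau; mutant
collapse to ≤ 8% of peak after D15) and flat for the rest, including the
retained Ors. Or-like genes carry a −4.5 log offset on base abundance: Or
transcripts in whole-antenna bulk come from sparse ORNs and sit far below
housekeeping levels; at desk scale (290 of 1,200 genes) leaving them at
housekeeping abundance lets their genotype-by-stage interaction dominate
the sample PCA, which it cannot in a real ~15k-gene transcriptome. The
acceptance check of stage-set recovery uses `loading_set_size` = 150 to
match the 150-gene programs (the production default 750 exceeds what a
1,200-gene panel supports with disjoint sets).

**Cluster pair**: 100 tandem genes, true-partner identity U(86, 96),
paralog identity decaying from ~57 with offset, alignment length 1,200
(paralogs 85%), bit = 2 × identity% × length; 10% of B-side gene models
truncated to 30% length (deflating all their bit-scores; identity
untouched), 5% of B genes collapsed (removed with all their rows).

## Determinism and numerics

All randomness flows from `PipelineConfig.rng_seed` through named
per-stage substreams (CRC32 of the stage name as spawn key), so stage
reordering cannot change within-stage draws. Output TSVs use fixed float
formatting (`%.6g`, `\n` endings); two runs from identical inputs and
config are byte-identical. PCA uses full SVD with a fixed sign convention;
kNN is exact; Leiden is seeded. Exact Mann–Whitney enumeration caps at
n+m = 12 (C(12,6) = 924 splits). Degenerate inputs have defined behavior
throughout: all-tied rank tests give p = 1, empty categories are dropped
with a log line, zero-variance concordance axes are reported missing,
genes absent from a matrix are skipped with a warning.

## Problem sizes

The shipped tests and the acceptance script run at the generator's default
desk scale: 2,000 cells per genotype, 1,200 genes, 24 bulk samples,
100-gene clusters (20 fixture replicates for the ID-transfer and
fold-change checks). These sizes keep every stage's statistical target
measurable (binomial error on recovered fractions ~1 pp) while the whole
suite completes in well under a minute per end-to-end run.

## Known limitations

- The orco+Ir+irco survival ratio is estimated from the ~40–90 cells per
  genotype that the 67%/12% design arithmetic leaves available; its
  run-to-run spread (CV ≈ 0.2) is inherent at this scale.
- The category rule table and the cluster-marker threshold are
  reconstructions of underdocumented choices; both are configurable data.
- The retained-Or cutoffs, synteny gap penalty, and identity floor have no
  published values; defaults are exposed and reported in outputs.
- Published concordance statistics (e.g. cross-platform R²) are
  data-dependent properties of the original sequencing data and are not
  reproduced by the synthetic conditions; the package reports the
  statistics it computes on its own inputs.
- No GO enrichment, phylogeny, alignment/UMI counting, or imaging-derived
  quantities; similarity tables for ID transfer are consumed, not computed.
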