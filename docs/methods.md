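# Methods

## Overview

`methylscreen` implements a promoter-centric analysis of DNA methylation
beadarray data (Infinium 450K-style β values) for tumor cohorts, together
with the downstream analyses that such data support: aberrant-methylation
calling against normal controls, unsupervised detection of CIMP-like
high-methylation subgroups, an integrated screen for methylation-silenced
genes re-activated by the demethylating agent 5-aza-2'-deoxycytidine
(5-aza-dC), quantification of locus methylation by qMSP PMR, and
classification of primary–metastasis pairs as clonal or parallel evolution
from shared and private promoter methylation.

## Genomic blocks and β values

The β value of a CpG site is the fraction methylated, from 0 to 1. Probes
are grouped into *genomic blocks* by the key
(gene, TSS-relative category, CGI relation, CGI id); a probe annotated to k
genes contributes to k blocks, and probes with no gene annotation group
under a null gene. The block β is the arithmetic mean of the non-missing
member-probe βs — averaging emphasises densely methylated islands, which
are the regions relevant for transcriptional silencing. A block's value is
missing only when all member probes are missing.

The exact grouping rule behind published block counts on the commercial
450K manifest is not standardised; the key above uses the standard Illumina
annotation axes and is documented so the block count is reproducible on any
manifest. The N/S directionality of shores and shelves is collapsed to
Shore/Shelf, since no analysis here uses it. Coordinates are 1-based, as in
Illumina manifests; only autosomal probes are analysed.

## Three-state methylation calling

Block β values are discretised as

| state | tissues | cancer cell lines |
|---|---|---|
| unmethylated | [0, 0.2) | [0, 0.2) |
| partially methylated | [0.2, 0.4) | [0.2, 0.8) |
| methylated | [0.4, 1.0] | [0.8, 1.0] |

Cell lines are near-clonal, so intermediate β values there indicate allelic
or regional heterogeneity rather than a methylated subpopulation; hence the
wider partial band. Published range notation overlaps at the endpoints
("0–0.2", "0.2–0.4"); we resolve it as half-open lower intervals with the
methylated class inclusive at its lower bound (β ≥ 0.4 / β ≥ 0.8), matching
the "β ≥ 0.4" convention used for gene lists.

## Aberrant-methylation calling

A block is aberrantly methylated when it is unmethylated (β < 0.2) in
*every* normal sample and methylated (β ≥ 0.4) in at least
`min_tumor_count` tumors (default 6, i.e. "more than 5 of 28").
"Unmethylated in the normal" is read strictly (every normal below
threshold) for determinism and consistency with the state scheme. The
reference set for per-sample summaries is the *normally unmethylated
CpG-island blocks* — island blocks unmethylated in all normals — and the
methylated-CGI fraction of a sample is the share of those reference blocks
in the methylated state (over blocks with non-missing β).

## Clustering

Unsupervised agglomerative clustering of samples uses Euclidean distance
over block β vectors. The linkage method is configurable
(complete / average / ward; default complete, the historical default of the
R clustering stack). Feature sets larger than an element cap (default
20,000 blocks) are reduced by a seeded uniform random subsample, recorded
in the result for reproducibility. Blocks with a missing value in any
clustered sample are dropped (Euclidean distance is undefined on missing
cells). Samples are sorted lexicographically before linkage so the tree is
invariant to input column order. "Most variable" blocks are ranked by
sample variance (standard deviation gives the same ranking) with ties
broken by block id.

## Expression and the induction screen

Expression arrays are scaled so the 75th percentile of all probe-level
signals in each sample equals 1.0 (linear-interpolation percentile; the
original software's convention is unknown, so ours is documented), then
averaged over each gene's probes. A gene is *expressed* in the mesenchymal
stem cell (MSC) / osteoblast (OB) baseline when its mean normalized signal
is ≥ `baseline_threshold` (default 0.5 — no published cutoff exists; the
default is explicit and configurable) in both cell types. Induction by
5-aza-dC is the log2 treated/mock ratio on signals floored at 0.01
(normalized scale) to keep ratios finite; a gene is induced when the ratio
is ≥ `induction_log2_threshold`. The default is 1.0 (two-fold); published
wording mixes "two-fold" with "signal log ratio > 2", so the threshold is
configurable rather than guessed.

## The integrated silencing screen

The eligible gene universe contains genes that (i) have a TSS200 CpG-island
block unmethylated in normals and methylated in ≥ `min_tumor_count` tumors,
(ii) are expressed in the MSC/OB baseline, and (iii) are evaluable on the
expression platform. A gene with several qualifying promoter blocks is
represented by the block methylated in the most tumors. A universe gene is
a candidate methylation-silenced gene when its promoter block is methylated
in the screened cell line under the cell-line scheme (β ≥ 0.8) and its
expression is induced by 5-aza-dC. The cell-line methylation requirement is
not part of the published three criteria and can be disabled
(`require_cell_line_methylated=False`) for a pure induction screen; it is
on by default because it attributes the induction to demethylation of the
gene's own promoter. Candidates sort by log2 induction (descending), ties
by gene symbol. Promoter demethylation under treatment is reported as the
β decrease in percentage points per gene.

## qMSP PMR

PMR = ((sample meth / sample Alu) / (reference meth / reference Alu)) × 100,
where the reference is SssI-treated fully methylated DNA. Alu repeats
normalize DNA amount because their copy number is little affected by
cancer-associated aneuploidy; consequently PMR is invariant to rescaling
both of a sample's counts by a common factor. Replicate wells are averaged
on the molecule-count scale (counts are the measured quantity). PMR values
above 100 (assay noise exceeding the reference) are reported with a
warning, never clamped.

## Clonal versus parallel evolution

For a primary–metastasis pair, the aberrant set of each lesion is the set
of universe blocks (TSS200 CpG islands unmethylated in normals, genes
expressed in MSC/OB) with β ≥ 0.40. With P and M the primary and
metastasis sets, the shared fraction of the primary is |P ∩ M| / |P|. The
pair is *clonal* when that fraction is ≥ `shared_fraction_min` (the
metastasis retains the primary's aberrant methylation, with or without new
private events) and *parallel* when the fraction is lower and the
metastasis has private events. No published numeric boundary exists; the
default 0.75 operationalizes "in addition to those detected in the primary"
versus "only a fraction", and is configurable. A pair with low shared
fraction but no metastasis-private events fits neither picture; it is
reported clonal with a logged warning rather than silently assigned.
Classification is undefined (an error) when the primary has no aberrant
methylation.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, with
planted ground truth:

- **Manifest** — per gene: a TSS200 island block (2–5 probes), a
  first-exon island block sharing the CGI (1–2), an upstream shore block
  (1–2), and a gene-body open-sea block (1–3); 500 genes → 2,000 blocks.
- **β values** — per-state Beta distributions reproducing beadarray
  bimodality: unmethylated mean ≈ 0.05 (Beta(2, 38)), partial mean 0.5
  (Beta(5, 5)), methylated mean ≈ 0.85 (Beta(17, 3)); cell lines draw
  near-binary values (Beta(2, 58) / Beta(60, 6)). A noise-free mode uses
  the point masses 0.05 / 0.5 / 0.85 (0.90 for methylated cell lines).
- **Planted structure** — 10% of islands are methylated in normals
  (imprinted-like); aberrant promoter blocks (fraction of all blocks,
  default 2%) are methylated in 10–28 of the 28 tumors; a 10-tumor
  high-methylator subgroup shares an extra ~20% of the normally
  unmethylated islands; 50 silenced genes are methylated in the cell lines
  and induced 4-fold by treatment, with a per-gene planted promoter
  demethylation uniform on 18–51 percentage points; three matched
  metastases follow the clonal model (two) and the parallel model (one).
- **Expression** — point-mass gene levels (expressed 2.0, silent 0.05 on
  the normalized scale) times a fixed per-probe log-normal affinity
  (σ = 0.25, shared across samples, as hybridization efficiency is) and
  per-cell multiplicative log-normal noise (CV 10%). Each cell line
  expresses its own program on top of the baseline set, keeping a
  substantial expressed population in every array — the condition under
  which 75th-percentile normalization is meaningful. A per-sample raw
  scale factor (uniform 50–200) makes normalization do real work.
- **qMSP** — Poisson counts around expectations consistent with the true
  PMR (scale 1,000 molecules by default); exact in noise-free mode.
- **Pairs** — clonal: metastasis = primary (40 blocks of a 100-block
  universe) plus 10 private events; parallel: 15 ancestral blocks plus 15
  independent private events per lesion. Optional per-block membership
  flips model call noise.

Randomness uses one named NumPy `default_rng` stream per product, seeded
from (master seed, CRC32 of the stream name), so adding one simulation
never perturbs another and every output is a deterministic function of the
config.

What the generator does **not** emulate: probe-level spatial
autocorrelation and type-I/II probe chemistry differences, tumor purity
gradients and copy-number effects on β, batch effects, continuous
expression-level distributions (levels are two-point up to affinity), and
cross-hybridization. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical structure, not robustness to
every artefact of real arrays.

## Problem sizes and numerical choices

Validation uses cohorts of 500 genes (2,000 blocks; 2,000 genes / 8,000
blocks for the screen), 28 tumors, 3 normals, and 2 cell lines — large
enough that planted structure dominates sampling noise while the full suite
runs in seconds. The aberrant-recovery checks use cohorts with exactly 40
planted aberrant blocks (no silenced genes, no high-methylator extras) so
precision is measurable against an unambiguous truth set. Block means are
exact arithmetic means (no weighting by probe count); tie-breaks everywhere
are lexicographic on identifiers; percentile and variance conventions are
NumPy/pandas defaults (linear interpolation, ddof = 1). β values outside
[0, 1] and malformed annotations are rejected at load time.

## Known limitations

- Published dataset-level counts (e.g. block totals on the commercial
  manifest, specific gene lists) depend on the vendor manifest and deposited
  cohort data and are not reproduced here; the pipeline reproduces the
  *procedures* and validates them on planted truth.
- The clonal/parallel boundary and the baseline expression cutoff are
  interpretations with documented defaults, not measured constants.
- Hierarchical clustering recovers the planted two-group structure; with
  `high_methylator_extra_fraction = 0` there is no structure to recover and
  the cut at k = 2 is arbitrary, as the null simulation test documents.
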