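# Methods

`chromfate` re-implements, as a tested pipeline, the bespoke computational
procedures of a bivalent-chromatin study of Uhrf1-deficient mouse embryonic
stem cells: Poisson ChIP/input enrichment calling, four-state promoter
classification with wild-type-to-knockout transition analysis,
transcription-factor binding-fate (loss vs replacement) classification,
ATAC nucleosome-free accessibility comparison, transcriptional-module
clustering, and AP-MS interactome filtering. Every stage runs on synthetic
data with planted truth, so each procedure's recovery behaviour is
measurable without external downloads.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention), everywhere,
including printed output. Fragments are assigned to windows and bins by
their midpoint `floor((start + end) / 2)`: each fragment is counted exactly
once, so window counts are sum-conserving and the genome-wide binned track
sums to the library size. Strand is carried on intervals but ignored by
counting — promoter windows are symmetric around the TSS, so strand cannot
change them. Normalization is counts per million mapped fragments (CPM).

## The Poisson enrichment test

For a window with ChIP count `k`, the null rate is the input's CPM
(plus a pseudocount) rescaled to the ChIP library depth:

    lambda = (input_cpm + pc) * chip_library_size / 1e6
    p      = P(X >= k),  X ~ Poisson(lambda)

with `pc = 0.5` CPM added to both libraries before ratios and rates
(avoids infinite ratios and zero rates on empty windows; the value is a
package choice). The fold gate is `log2((chip_cpm + pc)/(input_cpm + pc))
> 1` (a two-fold difference) and the significance gate is a
Benjamini–Hochberg adjusted p below 0.05. BH is implemented in-package as
the standard step-up (it is a core primitive of the pipeline and is
cross-checked against `statsmodels` in the tests); it is applied separately
per direction across all windows of a run — the package reads the
procedure as one test per window genome-wide.

Depletion is defined symmetrically: the input count tested against the
ChIP-implied rate. Consequently `call_differential_windows(input, chip)`
returns exactly the mirror image of `call_differential_windows(chip,
input)` — a property the tests assert.

Note a known limitation: the test conditions on the observed input count
as if it were the true rate. When both libraries are shallow (tens of
fragments per window), joint fluctuations produce occasional rejections
that a binomial two-sample test would not make. This is inherent to the
ChIP-vs-scaled-input Poisson formulation; the default synthetic depth
(about 100 fragments per 10-kb window, typical of 20–50M-read libraries on
a mammalian genome) is in the regime where the procedure behaves well.

## Sliding-window region calling and boundary refinement

Windows of 10 kb tile each chromosome at a step of `window/5 = 2 kb`
(the step is not stated by the underlying method description; window/5 is
fine enough to localize regions at desk scale). Significant windows
passing the fold gate are merged when overlapping or adjacent. Because any
10-kb window overlapping a strong region by as little as ~1.5 kb passes
both gates, the raw union overshoots a region boundary by most of a window
width; each merged candidate is therefore refined at quarter-step bins
(500 bp by default): a bin is kept when it passes the fold gate and a
Poisson test at a Bonferroni-corrected level (alpha divided by the
candidate's bin count, controlling spurious boundary extension within the
candidate), with two numerical choices that matter at bin scale —

- the null rate per bin uses the comparison library smoothed over a full
  window centered on the bin (a bin-sized input count is too noisy a
  denominator), and
- the pseudocount is half a fragment in count space (a CPM-sized
  pseudocount is far below one fragment at 500 bp, and zero-input bins
  would pass on noise alone).

The refined region is the longest consecutive run of passing bins, so an
isolated noise bin cannot stretch the span. On the default synthetic
regime (8x enrichment over 10-kb regions) this recovers planted regions to
the bin.

## Promoter states and transitions

H3K4me3 is quantified in TSS ± 2 kb, H3K27me3 in TSS ± 5 kb. A mark is
"present" when `log2(mark/input) > 1` and the BH-adjusted Poisson p (pooled
across all promoters of that mark in that condition) is below 0.05. The
two flags give four states: active (K4 only), bivalent (both), repressive
(K27 only), no_mark (neither). The transition table counts genes by
(WT state, KO state); row percentages and per-state retention (diagonal /
row sum) are derived from it. An empty WT class yields a missing retention,
never 0 — 0/0 is not a rate. Genes present in only one condition are an
error, not silently dropped.

## TF binding fates

Two peaks "overlap" when their edge-to-edge gap is at most 100 bp (gap 0
for intersecting intervals; distances are edge gaps because summit
positions are not available from BED intervals). Peak sets are compared
per set against the full other set — no one-to-one matching is forced, so
a peak is classified exactly once. A WT-specific Oct4 peak overlapping a
KO-specific Sox2 peak only is a Sox2 replacement; Nanog only, a Nanog
replacement; both, Sox2+Nanog replacement; neither, a loss. Targets are
assigned by nearest TSS to the peak midpoint, ties broken to the
lexicographically smallest gene id.

## ATAC comparison

Fragments of length strictly below 150 bp (sub-mono-nucleosomal) are kept;
150 bp exactly is removed. Per peak, WT and KO CPM counts give
`log2((ko + pc)/(wt + pc))` with `pc = 0.5` CPM, and the summary is a
two-sided paired t-test of the per-peak log2 ratios against 0 — paired
because the same regions are measured in both conditions (the unpaired
variant is defensible; pairing matches the measurement design). Identical
inputs give a degenerate test, reported as p = 1 with a zero-variance
flag rather than an error.

## Expression modules

Genes changing more than 1.5-fold (with a +1 pseudocount, because RPKM
matrices contain zeros) relative to the reference sample — WT at the first
timepoint, matching the "relative to WT at week 0" display convention —
are clustered by Ward linkage on Euclidean distances between
`log2(rpkm + 1)` profiles (scipy's `ward` on Euclidean input equals the
Ward.D2 variant), and modules are cut at dendrogram height 20. The height
value is kept as the default but exposed, since Ward merge heights grow
with cluster size and log-scale spread: it is calibrated to modules of
roughly a hundred genes and is not transferable across dataset sizes.
Module significance per timepoint requires both a >1.25-fold change of
mean member expression between conditions and p < 0.05 from a t-test
across member genes paired by gene; modules with fewer than two genes get
a missing flag.

## AP-MS interactome filtering

Proteins with fewer than two unique peptides, and proteins on a common
background list, are removed; normalization totals are computed over all
sequenced proteins *before* removal. Per replicate pair, the candidate
ratio is `bait_fraction / control_fraction`; when the control never saw
the protein the denominator is a pseudo-fraction of half a peptide over
the control total. A protein is a candidate when it reaches the two-fold
ratio in at least one replicate in which it survived prefiltering. With
unequal replicate counts, extra bait replicates compare against pooled
control fractions. Note the zero-control pseudo-fraction makes candidacy
of zero-control proteins scale-dependent in principle (doubling all counts
halves the pseudo-fraction); on any table where such proteins clear the
gate comfortably — including the packaged toy dataset — calls are
scale-invariant.

## The synthetic study

The generators are pure functions of a configuration and one seed; the
seed expands into fixed named substreams, so changing one component's
parameters never perturbs another's draws, and the full pipeline is
byte-reproducible. Defaults define the study conditions:

- **Genome/annotation**: two 50-Mb chromosomes; 2,000 genes with a minimum
  TSS spacing of 10.5 kb so neighbouring ±5-kb mark windows never overlap.
  The genome is large relative to the promoter windows (8–20%) because a
  total-count-normalized ChIP library whose reads are mostly signal
  acquires a composition bias that shrinks every measured fold; at these
  proportions a planted 4x window measures ~3x, as in real libraries.
- **ChIP**: per promoter window, input ~ Poisson(50) and ChIP ~
  Poisson(200) where the planted state carries the mark (4x), else
  Poisson(50); fragments uniform within the window; 600k background
  fragments per library placed outside the mark's windows so planted
  window rates are exact. Planted WT state frequencies are ESC-like
  (45% active / 25% bivalent / 15% repressive / 15% unmarked) and the
  default WT→KO transition matrix encodes the studied phenotype: bivalent
  promoters largely resolving to active or repressive states and
  repressive promoters frequently losing their mark.
- **Differential regions**: a dedicated 20-Mb chromosome, background
  0.01 fragments/bp (~100 per 10-kb window), six planted 10-kb regions at
  8x.
- **TF peaks**: 400-bp peaks; replacement peaks planted at edge gaps
  cycling 0/50/100 bp (all inside the 100-bp rule), plus decoy peaks at
  exactly 101 bp next to every fourth loss peak (just outside it).
- **ATAC**: 60% sub-150-bp fragments (lengths ~N(80,20) clipped below
  150, supra-nucleosomal ~N(220,40)); 300 peaks with ~30 expected sub-150
  WT fragments each; KO in-peak rates scaled by 0.5; 500k background
  fragments outside peaks.
- **Expression**: 4 modules x 100 genes over 4 timepoints x 2 conditions;
  module centers are distinct binary on/off time profiles separated by
  2 log2 units; per-gene log-normal noise SD 0.3 (log2); a 1.5x KO shift
  planted on modules 2 and 4 from the third timepoint on; 50 flat filler
  genes exercise the dynamic-gene filter.
- **Peptides**: planted interactors carry a four-fold raw excess (one with
  zero control counts, exercising the pseudo-fraction path); decoys draw
  counts whose ratio is bounded below two; background proteins are
  abundant in both channels.

What the generators do *not* emulate: GC and mappability structure,
duplicate reads, fragment-length/signal coupling in ChIP, peak-shape
profiles, overdispersed (non-Poisson) biological replication, and
annotation ambiguity (one TSS per gene). Passing recovery tests therefore
shows the procedures are correctly implemented and well-behaved under
their own model assumptions — not that those assumptions hold on any
particular real library.

## Problem sizes

Default runs use 2,000 genes on a 100-Mb genome (~5M fragments across
eight ChIP/input libraries), a 20-Mb region genome at 0.01 fragments/bp,
300 ATAC peaks over ~1M fragments, 450 expression genes, and ~60-protein
peptide tables — sizes chosen so a complete study, run twice for the
determinism check, finishes in well under a minute on one CPU while every
statistical regime (deep windows, boundary bins, null calibration) is
still exercised at realistic per-window depths.
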