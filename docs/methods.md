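# Methods

This note documents the models and procedures implemented in
`te-spectrum`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the package's known limitations.

## Coordinates and annotations

All internal coordinates are 0-based half-open. GTF (1-based inclusive)
and RepeatMasker `.out` are converted at the parsing boundary; BED passes
through. A gene's exons are pooled over all of its transcripts and merged;
the **first annotated exon** is the 5′-most exon in gene orientation
(min-start exon on `+`, max-end exon on `-`). A splice **acceptor site**
is the first base, in gene orientation, of every non-first exon: the
exon's genomic start on `+`, its genomic `end − 1` on `-`. Overlap queries
go through a per-chromosome interval tree whose results are
checked against a linear-scan oracle in the tests.

## Junction extraction

Junctions are read from the CIGAR `N` operations of primary alignments
only (secondary records of multimappers would double-count). A read with
*k* `N` operations contributes to *k* junctions; support is accumulated
per sample. Strand is taken from the `XS` tag when present, else unknown.
Alignments whose aligned portion begins or ends with an `N` are skipped
with a warning — such records carry no flanking exonic evidence.

## Chimeric transcript calling

A junction is called chimeric for gene *g* when

1. its **donor** (the last exonic base 5′ of the intron in gene
   orientation: `intron.start − 1` on `+`, `intron.end` on `-`) lies
   inside a TE instance;
2. the donor is strictly upstream, in gene orientation, of *g*'s first
   annotated exon;
3. the TE's gene-proximal edge is within **W** bp of the first exon's 5′
   edge (default W = 10,000; distances clamp at 0 when the TE overlaps
   the exon);
4. the **acceptor** equals an annotated acceptor site of *g*
   (`acceptor_tolerance` defaults to 0 bp — splice acceptors are
   base-precise in both simulated and aligned data);
5. at least `min_samples` samples (default 1) support the junction with at
   least `min_support` reads each (default 2, suppressing single-read
   artifacts).

When several TE instances contain the donor, the gene-proximal one is
reported. Junction strand must match the gene strand when known
(`require_gene_strand_match`, default on); TE strand matching is off by
default because LTR promoters can fire antisense to the element. Both are
switchable. Per-condition activity applies rule 5 within each condition's
replicates; a call active in one condition is *single-condition*, in all
conditions *ubiquitous*, otherwise *restricted*. The window, thresholds
and strand policy are explicit parameters rather than fixed truths: the
analyses this pipeline re-implements do not publish those settings, so the
defaults are the package's own documented choices.

## TE family quantification

Quantification is at the family level, the unit at which repeat activity
is normally reported; instance-level assignment exists internally for the
chimera stage. Two multimapper policies:

* **unique** (default): primary alignments with NH=1 (or no NH tag);
  a read is assigned to the family of the instance with the largest
  block-overlap; a tie between families discards the read as ambiguous.
* **fractional**: every reported alignment (primary and secondary)
  contributes 1/NH to its best-overlap family. Requires NH tags.

Both modes are verified against a brute-force per-read oracle. EM-style
reassignment (TEtranscripts-like) is out of scope.

## Differential expression engine

One engine serves genes and TE families.

* **Normalization**: median-of-ratios size factors. For TE testing, size
  factors can be computed from the gene count matrix so that genuine
  global TE activation cannot distort normalization.
* **Dispersion**: per-feature method of moments on normalized counts,
  pooled within groups: `α̂ = (s² − μ̂·E[1/s]) / μ̂²` (the `E[1/s]` term
  corrects the Poisson shot noise for size-factor scaling), then shrunk
  50/50 toward a trended least-squares fit `α(μ) = a₀ + a₁/μ` over all
  features. With fewer than two replicates in every group the engine falls
  back to a common dispersion (default 0.1) with a warning.
* **Test**: Wald statistic on the log2 fold change with delta-method
  standard error `SE² = Σ_g Var(μ̂_g)/((μ̂_g+pc)² ln²2)`,
  `Var(μ̂_g) = (μ̂_g·E[1/s] + α μ̂_g²)/n_g`, against a standard normal
  reference. The 50/50 shrinkage makes the plug-in SE well calibrated even
  at 3 replicates per group (empirical null type-I ≈ 0.066 at nominal
  0.05 in the Monte-Carlo suite; a t reference with residual df would be
  far over-conservative and was rejected for that reason).
* **Multiple testing**: Benjamini–Hochberg within each pairwise contrast;
  a feature is significant at |log2FC| > 2 and adjusted p < 0.01 (both
  configurable). The "robust" differential set is the union over all
  pairwise contrasts — per-contrast BH with union, rather than one global
  BH, is an explicit assumption of this package.
* The log2FC pseudocount defaults to 0.5 (guards all-zero groups);
  fold changes are identifiable relative to the unchanged majority of
  features, as is inherent to median-of-ratios normalization.

## Expression spectrum

Gene counts use primary NH=1 alignments whose blocks overlap exons of
exactly one gene; reads touching two genes are discarded rather than
split (the simplest defensible rule). The expression matrix is
transformed to log2(CPM + 1), restricted to the top `k_var_genes` most
variable genes (default 2000, clamped with a warning), gene-centered and
decomposed by SVD. Scores are `U·S`, loadings unit-norm columns of `V`;
`scores · loadingsᵀ` reconstructs the centered matrix to numerical
precision. The SVD sign gauge is fixed deterministically (largest-|loading|
positive per component) and PC1 is then re-anchored so the user-named
reference condition — the most naive state — has a negative mean score.
The **spectrum order** is the list of conditions sorted by mean PC1 score.
Correlation clustering uses Pearson correlation of the same transform with
average-linkage hierarchical clustering; samples are pre-sorted by id so
tied merges resolve deterministically.

A feature is flagged **TE-origin** when its TSS (5′ base of the first
exon) lies inside a TE instance or within `window` bp downstream of one in
gene orientation (default window 0, strict containment).

## Methylation

All levels are *weighted*: ΣM/ΣT pooled over the CpGs considered, never a
mean of per-CpG fractions — at the shallow coverages this pipeline targets
(1–3 reads per CpG) per-CpG fractions are uninformative while the pooled
estimator concentrates as coverage accumulates. A region whose summed
depth is below `min_depth` (default 10) reports a missing level, never a
silent zero. Region-set aggregates are the median of per-region levels
(the boxplot median of a feature class). Imprint status calls use the
package's own cutoffs, configurable: erased < 0.15 ≤ atrophied < 0.35 ≤
maintained ≤ 0.65 < hyper; genomic imprints are expected near 0.5 in
normal cells.

## Synthetic data

The generator emulates the structure of a multi-condition ESC profiling
experiment at desk scale. Defaults (chosen once, as study conditions):

* genome: 2 chromosomes × 1 Mb of uniform random sequence (~125,000 CpGs);
* six conditions — 2i/L, 2i/L_K, Pd/L, Ch/L, S/L, S/L_KD — ×3 replicates;
* 200 three-exon genes (10% lncRNA), 300 TE instances over 50 families
  with real family names (MERVL-int, MT2_Mm, IAPEy-int, ...); classes
  cycle LTR-heavy (50% LTR) to mirror the LTR dominance of repeat
  activation in pluripotent cells;
* gene counts NB with dispersion 0.1 around condition means built from a
  library of 30,000 reads/sample: 40 *gradient* genes follow a log-linear
  1 log2-unit/step trend along the condition order (alternating sign) and
  drive PC1; 40 *planted DE* genes are 8-fold activated in one condition
  each; 10 TE families are 8-fold activated in the naive half of the
  panel; 20% of TE reads are written as NH=2 multimappers (primary +
  secondary record, same read name);
* 30 planted chimeras (TE 0.5–2.5 kb upstream of the first exon, donor 50
  bp inside the TE, acceptor at the second exon) with 5 junction reads per
  active sample, active-condition patterns cycling
  ubiquitous / single-condition / half-panel; 5 *adversarial* chimeras
  identical in construction but 15 kb upstream — beyond the caller's
  window — which must never be called; 300 decoy junctions from ordinary
  gene splicing; 10 lncRNAs with a TE overlapping their TSS;
* per-CpG coverage Poisson(2); methylation binomial at per-condition
  global levels (0.27, 0.30, 0.57, 0.72, 0.77, 0.80 — the midpoints of
  the ranges the emulated culture series spans, hypomethylated 2i/L to
  hypermethylated serum) with 8 imprint regions at 0.5 except atrophy in
  2i/L (0.25) and erasure in 2i/L_K (0.05).

Everything derives from one seed through spawned generator streams;
identical configs give byte-identical files.

**What it does not emulate** — and hence what passing tests cannot show
about real data: sequencing error and quality, alignment ambiguity beyond
the simple NH=2 multimapper model, realistic TE sequence divergence and
nested/fragmented repeat structure, isoform complexity (one transcript
per gene), intronic/antisense transcription, paired-end geometry,
bisulfite conversion failure, covariate structure such as genetic
background, and batch effects. Recovery of planted signals demonstrates
the correctness of the rules and estimators, not their sensitivity on
real libraries.

## Numerical choices and degenerate inputs

Dispersion estimates are clipped to [1e−8, 20]; the trend fit falls back
to the median raw dispersion when fewer than 10 usable features exist.
All-zero features receive p = 1. Zero library sizes are rejected by the
CPM transform; zero-variance samples make correlation undefined and raise
an error naming the sample. Junctions on chromosomes absent from the
annotation are counted in a skip log rather than failing the run. Interval
ties in TE assignment are resolved by discarding (unique mode) or by the
gene-proximal instance (chimera TE choice). Pipeline stages skip when
their outputs are newer than their inputs unless `--force`; report JSON is
written with sorted keys and rounded floats so equal-seed runs are
byte-identical.

## Problem sizes

The shipped configurations run the full pipeline in about a minute on one
core: simulation ~20 s, counting ~25 s, the rest seconds. The Monte-Carlo
calibration suite uses 1,000 features × 20 seeds for the null and 1,000
features for power; oracle-equivalence fixtures use 1,000 random spliced
reads and 200 reads × 40 instances. These sizes give binomial/concentration
margins comfortably inside the asserted tolerances.

## Known limitations

* The DE engine is a two-group Wald test; no GLM with covariates
  (background, batch), no outlier refitting, no independent filtering.
* Family-level TE counting cannot separate instances with identical
  best-overlap geometry; no EM reassignment.
* The chimeric caller requires annotated acceptors — novel acceptors and
  TE-internal splicing are invisible; chimeric isoform abundance is
  summarized only by junction support.
* Imprint status cutoffs are definitions, not inferred thresholds.
* PCA ordering assumes the dominant variance axis is the state spectrum;
  with strong batch structure PC1 may capture something else, in which
  case the reference-condition anchor flags but does not fix it.
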