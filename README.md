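# te-spectrum

Mouse embryonic stem cells (ESCs) do not occupy a single "naive" state:
under different culture regimes (2i/LIF, 2i+KSR, PD/LIF, CHIR/LIF,
serum/LIF, ...) they settle into a *spectrum* of transcriptional and
epigenetic states. Each state carries a signature of transposable-element
(TE) activation — particularly LTR retrotransposons such as MERVL and its
MT2 promoter — and activated TEs can drive nearby genes by initiating
**chimeric transcripts** that splice from inside the element into the
gene's annotated exons. The spectrum is also coupled to a gradient of
global DNA methylation, with genomic imprints eroding in some naive
conditions.

`te-spectrum` is a desk-scale pipeline for mapping this spectrum from bulk
RNA-seq alignments and shallow whole-genome bisulfite CpG reports:

* **TE family quantification** with an explicit multimapper policy
  (`unique`: NH=1 primary reads, largest-overlap family assignment;
  `fractional`: every reported alignment contributes 1/NH), plus
  negative-binomial differential family activity and a per-class (LTR /
  LINE / SINE / DNA) breakdown.
* **Chimeric transcript calling** from spliced reads: a splice junction is
  called chimeric when its donor lies inside a TE instance that sits
  upstream of the gene's first annotated exon (within a window *W*, default
  10 kb) and its acceptor matches an annotated splice acceptor. Calls are
  classified per condition as ubiquitous / restricted / single-condition.
* **Expression spectrum ordering**: pairwise negative-binomial Wald tests
  across all condition pairs (|log2FC| > 2, BH-adjusted p < 0.01, union
  over pairs), sample correlation clustering, and PCA of log2(CPM+1) on the
  top variable genes. Conditions are ordered by their mean PC1 score, with
  the sign anchored so a user-named reference (most naive) condition sits
  at negative PC1; gene loadings report the drivers.
* **Methylome summaries**: weighted (read-pooled) 5-mC levels
  ΣM/ΣT globally, per region set (promoters, enhancers, repeats) and per
  genomic imprint, with imprint status calls
  (maintained / atrophied / erased / hyper).
* **A synthetic-data generator** that plants every one of these signals —
  graded expression, TE activation, multimappers, chimeric junctions,
  decoy junctions, adversarial chimeras beyond the window, condition-graded
  methylation with distinct imprint behaviour — so each stage is verifiable
  against known truth without any sequencing data.

The statistical core is a negative-binomial Wald test: counts are
normalized by median-of-ratios size factors, per-feature dispersion α is
estimated by method of moments from the pooled within-group variance
(Var = μ + αμ²) and shrunk 50/50 toward a trended fit α(μ) = a₀ + a₁/μ,
and log2 fold changes are tested with a delta-method standard error and
Benjamini–Hochberg correction within each contrast.

## Worked example

Run the full pipeline on the default simulation (six conditions × three
replicates, 200 genes, 300 TE instances over a 2 Mb genome, 30 planted
chimeras plus 5 adversarial ones, ~30,000 reads/sample):

```bash
te-spectrum run --out results/demo --seed 1 --json
```

The JSON report (about a minute of compute) contains, among others:

```
"spectrum_order": ["2i/L", "2i/L_K", "Pd/L", "Ch/L", "S/L", "S/L_KD"]
"global_by_condition": {"2i/L": 0.2712, "2i/L_K": 0.2981, "Pd/L": 0.5706,
                        "Ch/L": 0.7183, "S/L": 0.7682, "S/L_KD": 0.7983}
"chimera": {"n_calls": 30,
            "calls_by_specificity": {"restricted": 10,
                                     "single-condition": 10,
                                     "ubiquitous": 10}}
"de_genes": {"n_union_de_genes": 80}
"de_te":    {"by_class": {"LTR": 10, "SINE": 6, "DNA": 3, "LINE": 2}}
"truth_comparison": {"chimera_sensitivity": 1.0, "chimera_precision": 1.0,
                     "n_adversarial_called": 0, "de_union_sensitivity": 1.0,
                     "spectrum_spearman": 1.0,
                     "max_abs_global_methylation_error": 0.0019}
```

Reading it: PC1 of the expression matrix orders the conditions from the
hypomethylated naive 2i/L state to the hypermethylated serum state,
matching the planted developmental gradient exactly (Spearman 1.0); global
methylation rises monotonically along the same axis; all 30 planted
TE-gene chimeric transcripts are recovered with no false calls, and the
adversarial TEs placed beyond the 10 kb window are never called; the union
of pairwise differential genes (80 = 40 planted condition-specific genes +
40 gradient drivers) recovers every planted gene. Differentially active TE
families are dominated by the LTR class, as planted.

Individual stages are available as subcommands
(`simulate`, `te-quant`, `te-de`, `chimera`, `dge`, `pca`, `methyl`), e.g.

```bash
te-spectrum chimera --sam-dir sim/rnaseq --gtf sim/genes.gtf \
    --te-bed sim/tes.bed --design sim/design.tsv -W 10000 --min-support 2 \
    --out calls.tsv
```

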