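# zgaprime

Chromatin accessibility dynamics and transcriptional priming during
zygotic genome activation (ZGA).

In early zebrafish embryos, maternally deposited transcription factors —
Pou5f3, Sox19b and Nanog — open chromatin at promoters and enhancers before
the genes they serve are transcribed. `zgaprime` is a self-contained
reimplementation of the computational analysis behind that claim, for
people who want to study, stress-test or extend it: an ATAC-seq
fragment-to-statistics pipeline driven by a synthetic-data generator that
plants known effects, so every stage can be scored against ground truth
without downloading a single dataset.

## What it computes

Starting from paired-end ATAC fragment intervals (BED):

1. **Fragment processing** — Tn5 cut-site correction (start +4 bp,
   end −5 bp), nucleosome-free (NFR) split at 130 bp, 20 bp RPKM coverage
   tracks, TSS-centered and width-scaled region matrices.
2. **Peak calling** — per-bin Poisson enrichment over a genomic-DNA
   control with BH-FDR 5%, replicate confirmation (a pooled peak survives
   only if every replicate confirms it), and a cross-stage consensus set
   (single-linkage merge at ≥ 1 bp) with per-stage presence calls.
3. **Differential accessibility** — NFR counts over consensus peaks, a
   negative-binomial Wald test with trend-shrunk method-of-moments
   dispersions and total-fragment-count size factors; calls at
   |log2FC| ≥ 1.5, FDR < 5%.
4. **Annotation** — promoters as 2 kb TSS windows; putative enhancers as
   distal (≥ 1 kb from any TSS) consensus peaks bound by ≥ 1 core factor
   (Pou5f1/Sox2/Nanog ChIP) and ≥ 1 developmental factor; nearest-TSS
   linking within 20 kb.
5. **Dynamics** — k-means (k = 5, 10 starts) over stage FPKM trajectories
   with the between/within variance decomposition, plus 100-quantile
   heatmap binning.
6. **Priming statistics** — quintiles of accessibility increase
   (256-cell → oblong) against later expression with one-sided Wilcoxon
   tests; the 5 × 5 grid of increase × mutant-effect bins (median
   expression or z-scored H3K27ac per cell); TF enrichment by
   mutant-effect quintile; Welch and bound-combination comparisons.
7. **Motifs** — PWM best-hit scanning with exact DP score p-values,
   10-bin motif-score vs accessibility-loss analysis, Fisher enrichment in
   top-opening regions.

The statistic at the core is simple to state: for regulatory element *i*
with accessibility increase Δaᵢ = FPKM(oblong) − FPKM(256-cell) and
mutant effect βᵢ = mean over mutants of log2(mutant/wild-type), the
pipeline bins (Δaᵢ, βᵢ) into 20% quantiles and summarizes the later
expression of linked genes per bin — priming predicts the maximum median
in the (largest Δa, most negative β) corner.

## Worked example

The numbered scripts under `analysis/` run the whole study on a planted
synthetic dataset (250 genes, 600 regulatory regions, 23 ATAC libraries on
a 2 × 6 Mb genome) and narrate what they find:

```bash
python analysis/01_simulate.py
python analysis/02_peaks_and_consensus.py
python analysis/03_dynamics_clustering.py
python analysis/04_differential_mutants.py
python analysis/05_annotation_and_priming.py
python analysis/06_motif_analysis.py
```

On this dataset the run prints, among other things:

```
consensus: 405 peaks; 40 present at every stage
between-cluster differences explain 73.7% of total variance
MZpou5f3: 78 peaks lose accessibility, 1 gain (|log2FC| >= 1.5, FDR < 5%), of 405 tested
250 promoters; 204 putative enhancers, 204 linked to a gene within 20 kb
quintile medians (low -> high accessibility increase): [2.15, 1.95, 2.35, 2.99, 3.44]
priming grid maximum median 3.75 at (mutant-loss bin 1, increase bin 5)
median MZpou5f3 log2FC by pou-motif score bin (weak -> strong):
[0.07, -0.11, -0.03, -0.19, -0.11, -0.05, -0.17, -1.86, -2.15, -1.9]
```

Reading it: consensus peaks grow in number as chromatin opens across
stages; five trajectory classes absorb most of the variance; the planted
2^-2 depletion at Pou5f1-bound regions surfaces as ~80 called decreases;
genes behind the largest accessibility increases are expressed about 1.6×
higher at sphere stage than genes behind the smallest; the grid's maximum
sits in the priming corner (largest increase, largest mutant loss); and
accessibility loss in MZpou5f3 concentrates at the strongest pou-type
motif scores. All tables land under `results/`.

The same pipeline is available as a CLI (`zgaprime simulate`,
`zgaprime run-all`, plus per-stage subcommands) and as a library
(`zgaprime.pipeline.run`).

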