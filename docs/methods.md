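# Methods

`zgaprime` reimplements, as one tested pipeline over synthetic data, the
computational analysis of a chromatin-accessibility time course spanning
zebrafish zygotic genome activation (ZGA): seven developmental stages from
256-cell (before widespread transcription) to 80% epiboly (onset of lineage
specification), plus maternal-zygotic mutants of the maternal transcription
factors Pou5f3, Sox19b and Nanog assayed at oblong stage. The scientific
question the statistics address is *priming*: whether chromatin that opens
early — particularly chromatin opened by the maternal factors — predicts
which genes are transcribed later.

## Fragment processing

Input fragments are 0-based half-open BED intervals derived from properly
paired alignments (alignment, deduplication and quality filtering are
upstream of this package; a `mapq` column is honored when present).
Coordinates are corrected for the staggered Tn5 insertion by shifting starts
+4 bp and ends −5 bp; fragments whose corrected length falls below 1 bp are
dropped and counted. Corrected fragments are split at a nucleosome-free
(NFR) cutoff of 130 bp (length ≤ 130 is NFR); the cutoff is a parameter, and
`length_histogram` provides the fragment-length report from which such a
cutoff is chosen by inspection. All per-region quantification uses the NFR
fraction; the cutoff sits between the sub-nucleosomal (~80 bp mode) and
mono-nucleosomal (~180 bp mode) components of the ATAC length mixture.

Coverage tracks count fragment-base overlaps in fixed 20 bp bins, optionally
scaled to fragments per kb per million library fragments (RPKM). The peak
caller instead consumes `event_count_track` (one midpoint count per
fragment), because the Poisson model below needs approximately independent
per-bin counts; full-width coverage spreads each fragment over several bins
and inflates the apparent counts. Region matrices extract TSS- or
summit-centered windows (minus-strand rows reversed) or linearly rescale
each region to a 1000 bp window; out-of-chromosome positions are filled with
a declared fill value (default 0).

## Peak calling and consensus

Accessible regions are called against a naked genomic-DNA Tn5 digestion: the
control track is scaled to the treatment library, a local background rate is
the 2 kb moving average of the scaled control floored at its genome-wide
mean, and each bin receives the Poisson upper-tail p-value of its treatment
count. Benjamini–Hochberg at FDR 5% across all bins; significant bins merge
across gaps of ≤ 1 bin; peaks narrower than 100 bp are dropped; the summit
is the maximal treatment bin. Gap tolerance and minimum width are explicit
package choices, configurable. Peaks are called on pooled replicates and
kept only when they overlap (≥ 1 bp) a peak called in *every* individual
replicate. Replicated peaks from all wild-type stages are merged
(single-linkage, ≥ 1 bp overlap; abutting half-open intervals do not merge)
into the consensus set, and a consensus peak is "present" at a stage when it
overlaps a replicated peak from that stage.

## Differential accessibility

NFR fragments are counted over consensus peaks (≥ 1 bp overlap; a fragment
spanning two peaks counts in both). Size factors are the **total** fragment
count of each library — not the NFR count, and not a median-of-ratios
estimate. This matters: the NFR share of a library rises as chromatin opens,
so normalizing by NFR totals distorts cross-stage comparisons, while total
counts are stable by construction.

The test is a per-peak negative-binomial Wald test: method-of-moments
dispersions from within-condition residuals are shrunk (prior weight 10
pseudo-degrees of freedom against the residual df) toward a fitted trend
α(μ) = a₀ + a₁/μ, the log2 fold change uses condition means of normalized
counts with a 0.5 pseudocount, and its delta-method standard error feeds a
normal Wald reference. The normal (rather than t) reference is an empirical
calibration choice: with trend-shrunk dispersions the null rejection rate at
p < 0.05 sits at ≈ 0.047 in 2 v 2 NB simulations, while a t reference with
2 df is conservative by an order of magnitude. The suite verifies this
calibration and cross-checks fold-change estimates against pydeseq2 on a
planted fixture. Calls use |log2FC| ≥ 1.5 at FDR < 5%; all-zero peaks are
excluded and reported. Fold-change orientation is fixed: depletion in the
mutant/treated condition is negative.

## Regulatory elements and gene linking

Promoters are 2 kb windows centered on the TSS (clipped at chromosome ends,
flagged). Putative enhancers are consensus peaks ≥ 1 kb from every TSS that
overlap ≥ 1 core-factor ChIP peak (Pou5f1, Sox2/SoxB1, Nanog) and ≥ 1
developmental-factor ChIP peak (Smad2, FoxH1, Mxtx2, Eomesodermin, Ta,
Tbx16, Mixl1). Interval-to-TSS distance is 0 when the TSS lies inside the
interval, else the gap to the nearest edge — this makes "≥ 1 kb distal"
unambiguous, and guarantees promoters and enhancers are disjoint whenever
distal_min ≥ half the promoter window. Elements link to the nearest TSS
within 20 kb; equidistant ties break deterministically (lower coordinate,
then lexicographic gene id), and each element links to exactly one gene.
Gene classes from expression tables: expressed at a stage when RPKM ≥ 1.0;
late-activated when expressed at the later stage but not the reference
stage; never-expressed when summed RPKM over all stages < 0.1.

## Dynamics clustering

Per-peak stage FPKM trajectories (replicates averaged) are clustered with
k-means: k = 5, 10 random starts, up to 1000 iterations, seeded. Raw FPKM is
the default (a log2(x+1) flag exists); labels are renumbered by descending
final-stage centroid purely for stable presentation. The between-cluster
fraction of total variance is reported together with the exact decomposition
identity (between + within = total, checked to 1e-9 relative). The variance
fraction is data-dependent and is **not** asserted against any external
value. Heatmap matrices are binned into 100 joint rank quantiles:
bin(x) = ⌊F(x)·100⌋ with F the empirical CDF of all matrix entries, computed
in integer arithmetic so ties share bins and the mapping is exactly
monotone. The coefficient of variation across stages uses the sample
standard deviation (ddof = 1, configurable); zero-mean peaks are excluded
and counted.

## Priming statistics

Equal-frequency bins (quintiles unless stated) sort items stably by
(value, id) and cut so bin sizes differ by ≤ 1; ties at boundaries fall to
the lower bin, making binning order-invariant. The analyses:

* **Quintiles of accessibility increase** (256-cell → oblong FPKM change)
  vs later (sphere) expression of the linked gene, with one-sided Wilcoxon
  rank-sum tests (higher bin stochastically greater) for all adjacent pairs
  plus bin 1 vs bin 5. Elements sharing a gene reuse its expression (the
  plots are element-level); a deduplicated gene-level mode exists.
* **The 5 × 5 priming grid**: increase quintiles crossed with quintiles of
  the mean mutant log2FC (mean over the three mutants; `min` available),
  each cell the median outcome (or mean z-scored H3K27ac signal, z-scored
  across all regions before aggregation). Row 1 = greatest loss; column 5 =
  greatest increase. Empty cells are missing, not zero.
* **TF enrichment by mutant-effect quintile**: ChIP/Input signal (or
  signal over the genome-wide mean when no input exists) across bins of
  mutant effect, one-sided Wilcoxon that greater-loss bins carry more
  binding.
* **Welch t** comparison of element log2FC between genes down-regulated in
  the mutants and genes that are not; **paired one-sided t** for matched
  wild-type/mutant accessibility; **bound-combination analysis** of log2FC
  across the 7 non-empty subsets of {Pou5f3, SoxB1, Nanog} against the
  unbound reference.

Wilcoxon p-values use exact enumeration over rank assignments when both
samples have ≤ 8 observations (mid-ranks for ties) and the tie-corrected
normal approximation otherwise; when all pooled values tie, p = 1 with a
warning.

## Motif analysis

PWMs are position probability matrices (JASPAR count and MEME text readers)
scored as log2 odds against a 0-order background with a 1e-3 pseudocount.
Scanning slides both strands, N bases contribute zero log-odds, and the best
hit per sequence is kept. Score p-values are exact: the null score
distribution is computed by dynamic programming over the lattice of
log-odds rounded to 0.05 bits, verified against full enumeration for short
motifs. A best-hit window p-value is Šidák-corrected for the number of
windows scanned to give a per-sequence p-value; "has a hit" means the
corrected p ≤ 0.05. Without this correction every random 200 bp window
contains a nominally significant short-motif hit and presence/absence
enrichment is uninformative. Enrichment of the top-20% opening regions uses
the one-sided Fisher exact test on hit presence, BH across motifs, with an
optional family roll-up (minimum adjusted p, maximum hit fraction per
family). The three bundled matrices (pou-type octamer, sox-type, pou-sox
composite) are **synthetic stand-ins** built from consensus-plus-noise
counts; they are not database entries, and files/IDs say so.

## The synthetic study

The generator plants every effect the pipeline is asked to recover; its
defaults are the study conditions.

* **Design**: 7 stages with the study's replicate structure (2 replicates
  at 256-cell, sphere, shield, 80% epiboly; 3 at high, oblong, dome);
  3 mutants × 2 replicates at oblong; a transcription-inhibited condition
  (planted with no accessibility effect, matching the biology it mimics);
  a structureless genomic-DNA control.
* **Regions and trajectories**: each gene carries 1–3 regulatory regions
  (promoter-class within ±1 kb of the TSS; enhancer-class 2–16 kb away,
  always ≥ 1 kb from every TSS and linkable within 20 kb). Five trajectory
  archetypes (always-open, ZGA-opening, two gastrulation-opening shapes,
  flat background) are assigned **per gene**, regions inheriting the gene's
  archetype — a gene's elements open coordinately, which is also what makes
  element-level priming statistics informative. The archetypes deliberately
  differ in their 256-cell → oblong increments (7, 3.5, 0.5, 0, 0 relative
  units) so that early-increase quantiles map onto interpretable classes.
* **Counts**: negative-binomial per region and sample (dispersion 0.05)
  with multiplicative log-normal region × replicate noise (sd 0.25 on the
  log scale, consistent with replicate correlations ≈ 0.9 at one order of
  magnitude of signal spread). Every library has the same expected depth;
  the uniform background absorbs whatever the regions do not take, so the
  fraction of fragments in regions rises as chromatin opens, as in real
  ATAC libraries. Fragment lengths are truncated log-normals (modes ≈ 80
  and ≈ 180 bp) on either side of the 130 bp cutoff; emitted coordinates
  un-apply the +4/−5 shift so processing recovers planted positions
  exactly.
* **Binding**: enhancers carry ≥ 1 core and ≥ 1 developmental TF; half of
  promoters carry core factors. Each bound factor gets a continuous
  occupancy strength ~ U(0.5, 1.5) that scales the mutant depletion
  (mean × 2^(−2·strength) by default), the ChIP/Input ratio (4^strength),
  and the expression contribution — strong sites lose the most
  accessibility in mutants, the planted analogue of the motif-strength
  relationship.
* **Expression**: sphere-and-later RPKM = 1.5 + 1.0 × (planted increase) +
  0.75 × (mean summed core occupancy of the gene's elements) + N(0, 0.5),
  floored at 0; 10% of genes are planted silent (summed RPKM < 0.1).
  Early stages carry near-zero maternal-free values.
* **Reproducibility**: every output file draws from its own RNG stream
  derived from the master seed and a stable label, so regenerating one
  file never perturbs another; identical config + seed gives
  byte-identical files.

What the generator does **not** emulate: mappability and GC structure, read-
level error and duplicates, the genome-wide slow accessibility creep outside
regulatory elements, single-cell heterogeneity, miR-430-style
transcription-dependent accessibility, and any coupling between TF binding
and trajectory class (binding is independent of the archetype, so motif
enrichment *in top-opening regions* is not planted even though
motif-strength vs mutant-loss is). Passing tests therefore demonstrate that
the statistical machinery recovers known effects under a faithful-but-
idealized noise model, not that it would navigate every artifact of real
libraries.

## Problem sizes

The bundled analyses run at desk scale, chosen for stable statistics rather
than realism of genome size: the `analysis/` scripts use 250 genes /
600 regions / 150k fragments per sample on a 2 × 6 Mb genome; the
end-to-end demo behind the smoke acceptance test uses 800 genes /
2000 regions / 400k fragments on 2 × 18 Mb, sized so that each 5 × 5 grid
cell holds ≳ 25 linked elements and the corner-cell comparison is powered.
Null-calibration simulations use 2000 peaks × 10 replicates; priming power
uses n = 2000 elements × 50 replicates, with the planted effect entering
through a continuous increase covariate (the archetypes' 5-valued planted
increase leaves bottom-quintile medians tied, under which "strictly
monotone" is undefined rather than false).

## Known limitations

* The peak caller is a deliberately simple Poisson bin test; it has no
  fragment model, no multi-scale background, and is not a drop-in for a
  production caller (an adapter can ingest externally called peaks).
* Dispersion shrinkage uses a fixed prior weight rather than an empirical
  Bayes fit; adequate at these sizes, verified by simulation, but not a
  DESeq2 replacement on real data.
* One-gene-per-element linking ignores multi-gene regulation, and the
  generator's link structure (each region's host gene is its nearest gene)
  makes nearest-TSS linking nearly always correct — real enhancer–gene
  maps are harder.
* The generator's gene activation is binary at sphere; the "late-activated"
  gene class is therefore sparse in synthetic runs.
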