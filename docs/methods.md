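# Methods

`platepool` implements the data-processing side of a pooled, plate-based
single-cell RNA-seq protocol: each well of a 96-well plate holds capture
beads carrying a well-specific 6-base cell barcode, a 7-base unique
molecular identifier (UMI) per capture oligo, and a poly-T tail. After
pooling, amplification and paired-end sequencing, Read 1 (20 bases) carries
barcode + UMI + poly-T pad and Read 2 (50 bases) carries a 3'-biased
transcript fragment. The package reconstructs a digital gene expression
(DGE) matrix from such reads, runs species-mixing ("barnyard") quality
control, and provides the drug-response analysis stack, together with a
simulator that generates reads with known ground truth so that every stage
is testable without external data.

## Read simulation

**Reference.** Two synthetic species ("A" and "B") each contribute
`n_genes_per_species` transcripts of i.i.d. uniform DNA (default 300
bases). A fraction of genes per species (`floor(n * mito_fraction)`,
default 2%) is flagged mitochondrial. Random 300-mers are effectively
unique, so every gene is uniquely mappable; consequently the assignment
stage's ambiguity handling is exercised with purpose-built fixtures rather
than by the default reference.

**Plate and barcode whitelist.** A plate is a list of wells: cell wells
(one species each), negative-control wells (beads, no cell), and doublet
wells (two cells of different species under one barcode). Barcodes are
6-mers chosen by a randomized greedy search with a pairwise Hamming
distance floor. Distance >= 3 makes single-substitution rescue provably
unambiguous, but the 6-mer code space cannot support arbitrarily large
distance-3 sets: a linear [6,4,3] code over GF(4) does not exist (it would
be MDS, excluded for k=4 at length 6 over GF(4)), and randomized greedy
search saturates near ~100 codewords. The builder therefore guarantees
distance >= 3 for plates up to roughly 80–90 wells and otherwise keeps a
maximal distance-3 core and fills the remainder at distance >= 2. At
distance >= 2, a single substitution still can never be *mis*-assigned to a
wrong well — an observed barcode within distance 1 of two whitelist entries
is rejected as ambiguous rather than guessed — but a guaranteed rescue is no
longer possible for every barcode. Full 224-well (96+96+32) and 288-well
drug plates use this hybrid whitelist.

**Expression.** Per cell well, the total molecule count is Gamma–Poisson
(negative binomial) with mean `mean_molecules_per_cell` (default 5000,
a realistic per-cell capture at moderate sequencing depth) and dispersion
`dispersion` (default 0.1, i.e. variance `m + 0.1 m^2`). Totals are
allocated to genes multinomially according to a per-species abundance
profile (lognormal weights, sigma = `profile_sigma`, default 1.0).
Treatment effects are supplied as a (gene, condition, log2FC) table; a
gene's rate is multiplied by `2^log2FC` before allocation, so planted fold
changes are mildly attenuated by the implicit renormalization (negligible
when few genes are perturbed). Doublet wells superimpose two cells, one
per species, the second scaled by `doublet_ratio` (default 1.0, a 1:1
heterogeneous doublet). Every well additionally receives ambient
molecules — Poisson with mean `ambient_fraction * mean_molecules_per_cell`,
drawn from the pooled two-species profile — emulating free transcripts
captured during pooling; negative wells therefore contain ambient material
only.

**UMIs.** UMIs are uniform 7-mers drawn per (well, gene). By default the
UMIs within one (well, gene) pair are kept at pairwise Hamming distance
>= 2 (`umi_min_distance=2`), so each true molecule is its own Hamming-1
equivalence class and noise-free processing recovers molecule counts
*exactly* — the pipeline's central identity contract. Setting
`umi_min_distance=1` relaxes this to plain distinctness, which permits
within-gene near-collisions that any Hamming-1 collapse necessarily merges;
that mode exists to stress the collapse stage, not for the identity tests.
Collisions across wells and genes are unconstrained in both modes. The
rejection sampler refuses more than 2048 molecules per (well, gene), well
below the ~4096-word packing capacity of distance-2 7-mer codes, and fails
loudly if sampling stalls.

**Reads.** Each molecule is sequenced `k >= 1` times with
`k - 1 ~ Poisson(duplication_mean - 1)` (default mean 3, emulating
PCR/optical duplication). Read 1 is `barcode + UMI + "TTTTTTT"`; the pad
imitates the oligo's poly-T tail and is ignored downstream. Read 2 is a
50-base window of the transcript whose start is jittered uniformly over the
last 150 bases (3'-biased capture). Substitution errors are applied
independently per base at `error_rate` on both mates (default 0.2%; no
indels, no adapter artifacts, constant qualities). FASTQ output is
gzip-compressed with a zeroed timestamp so identical runs are
byte-identical.

What the simulator does *not* model: fragment-length distributions, indels,
quality-score structure, gene–gene correlation modules, isoforms, intronic
reads, or genome-scale mapping ambiguity. Passing tests therefore
demonstrate the correctness of the processing logic under the stated
generative model, not performance on real sequencing data.

## Tagging and barcode correction

Read 1 is split positionally: bases 1–6 barcode, 7–13 UMI; shorter reads
are counted as malformed and skipped. Observed barcodes are first matched
exactly against the whitelist; otherwise a precomputed Hamming-1 neighbor
table either rescues the read to the unique whitelist entry at distance 1,
or rejects it (ambiguous when two or more entries qualify, no-match when
none do). `N` counts as a mismatch everywhere. No quality filtering is
applied (a minimum-quality hook exists but defaults to off). UMIs are not
corrected at this stage; UMI collapse happens per (cell, gene) during
matrix construction.

## Transcript assignment

A seed-and-verify matcher stands in for genome alignment (deliberately out
of scope): transcripts are indexed by all k-mers (k = 21), candidate
(gene, offset) pairs come from three seeds sampled along the read, and a
candidate is confirmed if the whole 50-base read matches the transcript at
the seeded offset with at most `max_mismatches` substitutions (default 2,
tolerant of the simulator's error rate). The forward orientation is tried
first; the reverse complement is consulted only when no forward candidate
confirms. Exactly one confirmed gene → assigned; two or more → ambiguous
(discarded from counting, the common DGE convention for multimappers);
none → unassigned. The interface is pluggable, so externally produced
gene-tagged alignments could be substituted for the built-in matcher.

## DGE construction

Within each (cell, gene), distinct UMI sequences are collapsed to
equivalence classes: vertices are distinct UMIs, edges join pairs at
Hamming distance exactly 1, and the molecule count is the number of
connected components (identical duplicates share a vertex; chains merge
transitively). The directional, count-weighted collapse variant is *not*
used — with no read-count threshold specified, connected components is the
interpretation adopted, and it is the main interpretive choice of the
counting stage. Collapse is implemented by hashing each UMI's 21
single-substitution variants (linear in the number of UMIs) and is checked
in the tests against a brute-force all-pairs union-find oracle. Matrices
are written as Matrix Market triplets with `genes.tsv`/`barcodes.tsv`
sidecars, or as dense TSV; genes are ordered lexicographically, cells in
whitelist (plate) order, and whitelisted wells with zero reads keep their
zero columns.

## Barnyard QC

Per cell: total molecules, detected genes, mitochondrial fraction, and
per-species specificity (fraction of molecules from each species; the two
sum to 1 whenever the cell has data). Classification takes specificity
strictly greater than 0.9 for either species; everything else is
unidentified. A stricter 0.95 threshold is reported descriptively but never
used for calling. Filters: the transcript window keeps cells with totals in
[5000, 60000] inclusive (the "between" bounds are taken inclusive;
configurable); the gene filter requires the gene count to strictly exceed
500 and not exceed `max_genes` (default 6000, configurable up to 10000);
the mitochondrial filter requires the ratio strictly below 0.05. Ambient
RNA is estimated as mean negative-well total over mean identified-cell
total; its expectation under the generative model is `a/(1+a)` for
simulated fraction `a` (≈4.8% at a = 5%), a ~5% relative bias well inside
the 20% recovery tolerance used in the tests. Doublet flagging is the union
of two rules over non-negative wells: unidentified with a total above the
transcript ceiling, or unidentified with a total above
median + 3 × scaled MAD (1.4826 × median absolute deviation) of the
identified cells; with fewer than 3 identified cells only the fixed rule
applies. A 1:1 doublet carries only ~2× the median total, so single-doublet
detection is borderline by construction; the rule is designed to flag the
clear outliers the mixed-species signal has already made suspicious.

## Expression analysis

All analysis operates on `log2(CPM + 1)`; inverting the transform recovers
per-cell totals of exactly 10^6 (the identity is tested to 1e-6 relative).
Zero-total cells must be removed before normalization. Variable genes are
ranked by dispersion (variance/mean of CPM) z-scored within mean-expression
bins (20 bins, reduced automatically for small panels). PCA uses the top
components (default 4) of per-gene-centered values with a deterministic
sign convention (largest-magnitude loading positive). Clustering builds a
k-nearest-neighbor graph (k = 20) in PC space, weights edges by neighborhood
Jaccard overlap (shared-nearest-neighbor construction), and optimizes
modularity with a resolution parameter (default 1.5) using the Leiden
algorithm under a fixed seed; equivalence with any specific external
implementation is not promised — the contract is recovery of planted
structure on synthetic data.

Differential expression is a two-sided Wilcoxon rank-sum test per gene:
exhaustive enumeration of the permutation null of the rank-sum statistic
(midranks for ties, two-sided by symmetry about the null mean) when both
groups have at most 8 cells, otherwise the normal approximation with tie
and continuity corrections. The family tested per contrast is the genes
with nonzero counts in the union of the two groups; Benjamini–Hochberg
adjustment is applied per contrast independently. log2FC is defined as the
*difference of group means on the log2(CPM+1) scale* — note this differs
from ratio-of-means conventions and shrinks toward zero for weakly
expressed genes. A gene is called up (down) when log2FC > 0.25
(< −0.25) and FDR < 0.05. No fold-change prefilter is applied before
testing (a flag exists). The heatmap gene set is the union, across
drug-vs-control contrasts, of genes with FDR below `heatmap_alpha`
(BH-adjusted, the interpretation adopted for an ambiguous cutoff
convention; configurable).

Cell-cycle scoring: the S (G2M) score is the mean marker expression minus
the mean of an expression-matched background — 25 genes per marker sampled,
with a fixed seed, from the marker's mean-expression bin (25 bins, shrunk
for small panels). Phase is the argmax of the two scores when positive,
else G1. Batch correction fits, per gene, a linear model
`value ~ intercept + condition + batch` with the batch factor coded
sum-to-zero and subtracts only the fitted batch terms; it is exact for
additive per-gene offsets, preserves condition means up to the fit, and
rejects designs where batch is aliased with condition via a rank check.
Pseudobulk profiles are per-condition means of log2(CPM+1) with pairwise
Pearson correlations (R² = r²).

## Determinism and seeds

Every stochastic stage derives its generator from the run seed salted with
the stage name (CRC32), so stages can be rerun independently and full runs
are byte-identical for identical configuration and seed.

## Problem sizes used in the checks

The end-to-end noise-free identity check uses the full 224-well plate
(96 + 96 cells, 32 negatives) at a mean of 2000 molecules per cell with 3×
duplication (~1.1 million read pairs); ambient recovery uses the same plate
at mean 5000; DE calibration uses 5000 null genes at the 48-vs-144 group
sizes of the drug design, and sensitivity uses 40 planted 2-fold genes at
those sizes; the cross-batch check uses two 48-cell batches with per-gene
N(0, 2²) log-scale offsets planted in one batch, a deliberately strong
technical effect that drives the uncorrected cross-batch pseudobulk R²
below 0.9. These sizes are the package's chosen desk-scale study
conditions; the generative defaults above are not adjusted per check.

## Known limitations

- The transcript matcher is not a spliced genome aligner; real data would
  be processed by substituting externally gene-tagged alignments.
- Ambient estimation is a single scalar; no per-gene ambient profile is
  subtracted.
- Doublet detection formalizes a single-outlier heuristic; it is not a
  classifier built on synthetic doublets.
- Reported descriptive statistics of the original experiments (per-class
  gene/transcript means, species separation counts, the 262-gene heatmap
  list, cross-method comparisons against external droplet data) depend on
  real sequencing data and are computed by the machinery but not asserted
  to any published value.
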