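# Methods

This note records the models implemented in `zonescope`, the defaults
that matter, the design choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Barcode scheme and demultiplexing

A sequencing run is a trio of synchronized FASTQ streams: Read1 (36
nt), Index2 (8 nt), Read2 (127 nt cDNA). The platform only fixes the
total Read1 length and its content classes (cell barcode + SSS
barcode), not the internal layout, so the layout is configurable; the
default is cell barcode (10 nt) + UMI (8 nt) + SSS barcode (8 nt) +
spacer (10 nt). The UMI position in particular is a declared choice —
nothing downstream depends on where it sits, only that the scheme
locates it.

Pooling is nested: 10 cells per SSS barcode, 50 cells per Illumina
index, so a cell identity is the triple (index, SSS, cell). Default
whitelists are drawn at random subject to a pairwise Hamming distance
≥ 3 within each tier, which makes single-substitution correction
unambiguous; loading a whitelist that violates this raises a warning.
Correction accepts the unique entry within `max_mismatch` (default 1)
per tier and returns UNASSIGNED on ties or misses — with 26 barcode nt
per read and an error rate ε per base, the expected assigned fraction
is well approximated by the probability of at most one error per
segment, which at ε = 1% exceeds 0.98; the acceptance run measures
≈ 99% assigned with 100% cell accuracy, consistent with that bound.

Transcript assignment replaces genome alignment with k-mer voting
(default k = 21) against a toy transcriptome: a read goes to the gene
containing the most of its k-mers, MULTI on ties, NONE when the best
gene covers under half the read's k-mers. MULTI/NONE reads are
excluded from counting but tallied. This is a deliberate,
self-contained stand-in adequate for synthetic transcripts; it is not
a spliced aligner and makes no claim about genomic reads.

UMI collapse is exact deduplication of (cell, gene, UMI) by default.
The directional mode additionally merges a UMI into a Hamming-1
neighbor with count ≥ 2·count − 1 (the standard directional-adjacency
rule); it is off by default because the platform's own collapse method
is unspecified and exact dedup is the more conservative choice.

TPM: TPM_g = 10^6 (c_g/l_g)/Σ_j(c_j/l_j). All-zero cells stay zero with
a warning rather than erroring, since laser-lysed single-cell runs do
produce empty wells.

Zone binning is left-closed right-open on lesion-edge distance:
A [0, 200), B [200, 400), C [400, 600) µm; the distal zone D is
distance ≥ 1000 µm (the threshold is configurable — "distal" is only
qualitatively specified). Distances in [600, 1000) are labeled
`unzoned` and flagged, never silently binned.

## Quality control

Cell filters use strict inequalities exactly as quoted by their
source conventions: remove if detected genes < 200, if detected genes
> 3800 (doublet proxy), or if mitochondrial fraction > 30% (mito
counts / total counts). The three rules are applied jointly, so the
surviving set is order-independent; the report attributes removals to
each rule and counts overlaps. Spot filters: spots with < 100 detected
genes are dropped first, then genes detected in < 5 spots.

The regularized NB regression normalization of the original toolchain
is replaced by analytic Pearson residuals with a fixed dispersion
θ = 100: r = (x − µ)/√(µ + µ²/θ) with µ from the rank-1 margin product,
clipped to ±√n_cells. This preserves the variance-stabilizing intent in
a closed, testable form; it does not reproduce per-gene regularized
parameter fits.

## Spatial analysis

Spot adjacency connects pairs closer than 1.2× the minimum pairwise
distance, which on a hex lattice yields the 6-neighborhood for
interior spots.

NMF minimizes the Frobenius loss by multiplicative updates from a
seeded uniform initialization, stopping at relative improvement
< 1e-5 or 500 sweeps. The per-iteration loss trace is recorded and
non-increasing (a property of multiplicative updates); tests also
check the reconstruction error is competitive with scikit-learn's MU
solver. The number of factors is k = 20 at study scale; the synthetic
section uses k = 3 because three programs are planted.

Moran's I uses binary (unnormalized) weights by default:
I = (n/S₀)·Σw_ij z_i z_j/Σz², with the local form
I_i = n·z_i·Σ_j w_ij z_j / Σz² (so Σ_i I_i = S₀·I). Constant inputs
return 0 with a warning. Because the per-spot "autocorrelation value"
of the original figure could be either local Moran or a neighbor-
smoothed loading, both are provided (`local_autocorrelation`,
`spatial_lag`).

Injury-factor selection scores each factor by mean loading inside a
region over mean loading outside (+ ε = 1e-9) and takes the argmax.
Spot clustering is k-means on the NMF loadings — the original
pipeline clusters a UMAP embedding, but UMAP is a visualization whose
structure is not deterministic; loadings (or PCs) carry the same
signal in a seeded, reproducible form. Border spots are the non-member
spots adjacent to ≥ 1 member of the target cluster. Injury-vs-border
DE is a per-gene Wilcoxon rank-sum on normalized expression with BH
adjustment; on residual-normalized input (which can be negative) the
effect size is reported as a mean difference and the log-ratio column
is left NaN.

## Single-cell mapping

Clustering: PCA (10 components) → kNN graph (10 neighbors) → greedy
modularity communities; singleton communities merge into the nearest
cluster by centroid distance with a warning. Marker criteria: ln fold
change > 0.25 computed as ln(mean_in + 1) − ln(mean_rest + 1) (the +1
keeps zero-mean groups finite and mirrors the source convention's
natural-log scale), detection in > 25% of in-cluster cells, BH-adjusted
rank-sum p < 0.05.

Label transfer replaces anchor-based integration with NNLS centroid
scoring: top shared variable features (standardized dispersion
ranking, default 2000), per-cluster reference centroids, per-spot
non-negative least squares, coefficients normalized to sum to one.
This preserves the probabilistic-score contract (non-negative, rows
sum to 1, a centroid query scores ~1 for its own cluster, mixtures
split proportionally) with a closed-form core. Spots whose best score
falls below 0.5 are flagged unconfident — the threshold for declaring
that a reference cluster "does not overlap" the tissue is a declared
choice, as no quoted value exists.

## Zone differential expression

Counts are modeled as y ~ NB(µ = s·m, φ) with per-sample size factors
s from the median-of-ratios estimator (robust to asymmetric DE;
total-count offsets demonstrably produce composition-bias false
positives when one zone carries strong enrichment). Dispersion:
per-gene method of moments pooled over zones,
φ̂ = Σ(n_z−1)(s²_z − µ̂_z) / Σ(n_z−1)·m2_z with m2_z = µ̂²_z − s²_z/n_z
the unbiased estimate of µ² (using µ̂² directly biases φ̂ low by
~5% at these sizes); the common value pools numerators and
denominators across genes; tagwise values shrink toward it with
weight prior_df/(prior_df + residual df). Negatives clamp to zero.

The default prior_df is 40 — deliberately heavy. The moment estimator
at ~16 residual df is far noisier than a Cox–Reid profile likelihood,
and at light shrinkage its per-gene noise inflates the LRT type-I
error to ~0.07–0.08; at prior_df = 40 the null simulation (2000
genes, 4 zones × 5 cells, φ = 0.2) is calibrated at 0.05–0.06 while
fold-change-8 genes are still detected with power ≈ 1 at FDR 0.05.

The LRT maximizes the NB log-likelihood per gene under zone-specific
means (per-zone Newton on log m, started from the closed-form Σy/Σs)
and under a single mean, referring 2Δℓ to χ²(zones − 1). Optimizing
each zone separately guarantees LR ≥ 0 by nesting. At φ ≤ 1e-10 the
likelihood degenerates to the exact Poisson closed form, where the
test agrees with a Poisson LRT oracle to machine precision.

Zone-group classification applies, to FDR < 0.05 genes, in precedence
order: (d) lncRNA with zone-B mean below the detection threshold but
detected outside B; (a) zone-B mean above every other zone; (b)
detected in A, C and D but below threshold in B; (c) mean over C,D
above mean over A,B with C and D each detected. The detection
threshold is TPM ≥ 1 — the original figure shows binary
presence/absence without a stated cutoff, so the rules are declared
interpretations; precedence makes the groups a partition.

## Zone proteomics

Proteins are kept when observed in ≥ 2/3 of the samples of at least
one zone. Samples are median-aligned before testing (standard LFQ
practice; the generator's global zone-B intensity deficit exists to
drive censoring asymmetry and must not masquerade as per-protein
effect). Missing values are imputed per sample from
Normal(mean − 1.8·sd, (0.3·sd)²) — the classic left-censored
down-shift; imputation is optional, since whether the original
analysis imputed or used available cases is unstated.

The moderated t-test shrinks pooled per-protein variances toward a
prior: (d₀, s₀²) are fitted by matching the mean and variance of
log s² against the scaled-χ² model (trigamma inversion; when the
observed spread does not exceed the χ² expectation, d₀ = ∞ and all
variances pool). t = diff/(s_post·√(1/n_A + 1/n_B)) on d₀ + d_g df.
Significance needs both BH-adjusted p < 0.05 and |log2 FC| > 1; the
fold-change cut is a hard gate, not a shifted null. Setting the prior
to 0 recovers the ordinary two-sample t-test exactly — tested at
1e-10 — and the Monte-Carlo benchmark (200 replicates, 10% planted
effects of |log2 FC| = 2, 5 vs 5) shows observed FDR ≈ 6–7% with
≈ 95% recall.

## Synthetic generators: what they emulate, and what they don't

All generators are byte-reproducible under a fixed seed, and a single
pipeline seed fans out to stage seeds through `SeedSequence`.

* **Transcriptome**: random uniform-composition sequences, ≥ 10%
  lncRNA, ⌈n/20⌉ mitochondrial genes. No homology, repeats, or GC
  structure — k-mer assignment is therefore easier than on a real
  transcriptome.
* **tDISCO runs**: zone programs share a gamma baseline with four
  planted groups (8× zone-B enrichment, B-silenced, 6× distal C/D,
  B-silenced lncRNA), planted on above-median-expression transcripts
  as in the clearly detected grouped genes of real zone heatmaps.
  Reads carry uniform substitution errors in barcode segments only;
  UMIs are error-free so molecule truth stays exact; quality scores
  are constant. PCR duplication re-reads an existing molecule with
  probability `umi_dup_rate`.
* **Visium sections**: a hex lattice at 100-µm spacing; the injury
  factor's loadings are strictly confined to a disc; other factors are
  smooth ramps vanishing on the disc, so planted factors are nearly
  spatially disjoint — real factors overlap far more. Counts are NB
  (φ = 0.2) around W·H.
* **Single cells**: NB counts from per-cluster programs with disjoint
  marker blocks and a condition label per cell (one cluster 90%
  injured by default). No batch effects, ambient RNA, or doublets.
* **LFQ tables**: Gaussian log2 intensities, probit left-censoring
  P(missing) = Φ((c − x)/w) with c = mean − 1.8·sd by default, and a
  −1 log2 global shift on zone B so the lower-intensity group loses
  more values.

Passing these benchmarks shows the implementations are correct and
calibrated under their stated models. It does not show robustness to
the things the generators omit: alignment ambiguity, overlapping
spatial programs, batch structure, non-Gaussian LFQ noise, or
peptide-level missingness. Desk-scale sizes (20–400 cells, 60–90
genes, 300 proteins, 20×20 lattices) were chosen so the full pipeline
and its Monte-Carlo benchmarks run in seconds while every planted
effect remains statistically recoverable.

## Degenerate inputs and tie-breaking

Barcode ties → UNASSIGNED; k-mer ties → MULTI; factor-gene ranking
ties break by gene id; all-zero TPM cells and constant Moran inputs
warn and return zeros; all-zero query spots get uniform transfer
scores; zero-variance rank-sum comparisons report p = 1; dispersion
estimates clamp at 0; BH caps at 1.
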