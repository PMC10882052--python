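# zonescope

Zone-stratified analysis of astrocyte heterogeneity around a cortical
stroke lesion, built as a fully synthetic, ground-truth-tested pipeline.

After an ischemic injury, astrocytes at different distances from the
lesion edge adopt distinct molecular states. Measuring this requires
stitching together four kinds of evidence: spatial transcriptomics of
the injured section, droplet single-cell RNA-seq of sorted astrocytes,
spatially indexed single-cell RNA-seq of individually laser-lysed cells
binned into 200-µm distance zones (A: 0–200, B: 200–400, C: 400–600 µm,
plus a distal zone D), and single-cell label-free proteomics of the
same zones. `zonescope` implements the complete computational path for
all four arms, and ships generators that simulate each input modality
with known ground truth, so every stage is tested by parameter
recovery rather than by eyeballing.

## What the package computes

**Read demultiplexing and counting** (`zonescope.reads`). Reads arrive
as a FASTQ trio: a 36-bp Read1 carrying the cell barcode, UMI and
second-strand-synthesis (SSS) barcode, an 8-bp Index2, and a 127-bp
cDNA Read2. Barcodes are nested — each SSS barcode pools 10 cells, each
Illumina index 50 — and are resolved tier by tier against whitelists,
accepting the unique entry within Hamming distance 1 and never guessing
ties. Read2 is assigned to a transcript by 21-mer voting, molecules are
deduplicated by UMI (exact, or directional Hamming-1 merging), and
counts are normalized to transcripts per million,

    TPM_g = 10^6 · (c_g / l_g) / Σ_j (c_j / l_j),

so every non-empty cell sums to 10^6.

**Quality control** (`zonescope.qc`). Cells are dropped when they
detect fewer than 200 or more than 3800 genes or exceed 30%
mitochondrial counts; spots need ≥ 100 detected genes and genes ≥ 5
spots. Normalizations: log-normalization ln(1 + 10^4·x/colsum) and
analytic Pearson residuals (x − µ)/√(µ + µ²/θ) under a fixed-dispersion
NB null as a variance-stabilizing transform.

**Spatial factors** (`zonescope.spatial`). Non-negative matrix
factorization X ≈ W·H by multiplicative updates (Frobenius loss, seeded
init, recorded non-increasing loss trace) decomposes the spot-by-gene
matrix into additive spatial programs. Factor loadings are scored by
global and local Moran's I over the hex-lattice adjacency graph,

    I = (n / Σ w_ij) · Σ w_ij z_i z_j / Σ z_i² ,

the injury-localized factor is the one maximizing mean loading inside
vs outside the lesion region, spots are k-means-clustered on loadings,
the border of the injured cluster is the set of adjacent outside spots,
and injury-vs-border differential expression uses Wilcoxon rank-sum
with Benjamini–Hochberg control.

**Single-cell mapping** (`zonescope.mapcells`). Cells are clustered by
PCA → kNN graph → greedy modularity. Markers follow the
one-vs-rest Wilcoxon rule with > 0.25 ln-fold change, > 25% in-cluster
detection and adjusted p < 0.05. Cluster labels transfer onto spatial
spots by non-negative least squares of each spot profile on cluster
centroids over shared variable features; the normalized coefficients
are probabilistic prediction scores (each spot's scores sum to 1).

**Zone differential expression** (`zonescope.zonede`). Counts per zone
are modeled as negative binomial with median-of-ratios size-factor
offsets. Dispersion is estimated per gene by method of moments
(var = µ + φµ², with an unbiased-µ² correction) and shrunk toward the
pooled common value; each gene is tested by a likelihood-ratio test of
zone-specific vs common means, LR ~ χ²(zones − 1), with BH-adjusted
p-values. Significant genes are classified into localization groups:
enriched in zone B (a), silenced in B (b), distal C/D (c), and lncRNA
silenced in B (d).

**Zone proteomics** (`zonescope.protde`). log2 LFQ tables with
left-censored missingness are filtered on per-zone detection, median-
aligned, imputed from a down-shifted Gaussian, and tested with an
empirical-Bayes moderated t-test: posterior variances
s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with (d₀, s₀²) fitted by moment
matching on log sample variances; a protein is significant when its
BH-adjusted p < 0.05 *and* |log2 FC| > 1.

## Worked example

Each analysis driver simulates its inputs, runs the corresponding
stages, and writes tables under `results/`:

```bash
python analysis/01_demux_and_zone_de.py --seed 0
```

prints

```
reads assigned: 7979/8000 (99.74%), cell accuracy 100.00%
molecules counted: 5645
planted zone-group recovery: {'a': '100%', 'b': '100%', 'c': '100%', 'd': '100%'}
16 genes differential across zones at FDR < 0.05
```

i.e. with a 0.5% per-base barcode error rate, 99.74% of the 8000
synthetic reads resolve through all three barcode tiers, every assigned
read lands in its true cell, and the NB-LRT plus the group rules
recover all sixteen genes planted into the four zone-localization
groups. The remaining drivers (`02_spatial_factors.py`,
`03_map_single_cells.py`, `04_zone_proteomics.py`) cover the spatial,
mapping, and proteomic arms the same way, and
`zonescope run-all --seed 0 --out results/` (or
`zonescope.run_all()`) chains everything into one recovery report.

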