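"""Synthetic data generators with recorded ground truth.

Every generator emulates one input modality of the zone-stratified
stroke-astrocyte study:

* a toy transcriptome (FASTA + gene metadata) against which reads are
  assigned by k-mer voting;
* tDISCO runs — FASTQ trios with nested barcode pooling (10 cells per
  SSS barcode, 50 per Illumina index), UMI duplication, per-base
  barcode substitution errors, and zone-specific expression programs;
* Visium-like sections — hex-lattice spot counts with a planted,
  spatially confined injury factor;
* single-cell count matrices with cluster programs and injury-condition
  labels;
* LFQ protein intensity tables with left-censored (MNAR) missingness
  that is worse in the lower-intensity zone-B group.

All generators are byte-reproducible under a fixed seed, and return the
ground truth needed by parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import io
from .errors import ConfigurationError
from .reads import BarcodeScheme, READ2_LEN

_BASES = np.array(list("ACGT"))

ZONES = ("A", "B", "C", "D")
#: [lo, hi) distance bins (µm from the lesion edge) for zones A-C; D is distal.
ZONE_DISTANCE = {"A": (0.0, 200.0), "B": (200.0, 400.0), "C": (400.0, 600.0), "D": (1000.0, 1500.0)}


# ---------------------------------------------------------------------------
# toy transcriptome


@dataclass
class ToyTranscriptome:
    """Synthetic transcript set: sequences plus per-gene metadata.

    ``genes`` columns: gene_id, length, biotype (protein_coding |
    lncRNA), is_mito.
    """

    genes: pd.DataFrame
    sequences: dict[str, str]

    @property
    def lengths(self) -> pd.Series:
        return self.genes.set_index("gene_id")["length"]

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(out_dir / "transcriptome.fasta", self.sequences)
        io.write_tsv(out_dir / "genes.tsv", self.genes)
        return out_dir

    @classmethod
    def read(cls, in_dir: str | Path) -> "ToyTranscriptome":
        in_dir = Path(in_dir)
        return cls(
            genes=io.read_tsv(in_dir / "genes.tsv"),
            sequences=io.read_fasta(in_dir / "transcriptome.fasta"),
        )


def make_toy_transcriptome(
    n_genes: int = 60,
    min_len: int = 300,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ToyTranscriptome:
    """Random transcriptome with ceil(n/20) mitochondrial and >=10% lncRNA genes.

    Mitochondrial genes are protein-coding genes named ``mt-...``;
    lncRNA genes are a disjoint set. Lengths are uniform on
    [min_len, min_len + 300).
    """
    if n_genes < 10:
        raise ConfigurationError("n_genes must be >= 10")
    if min_len < 200:
        raise ConfigurationError("min_len must be >= 200")
    rng = np.random.default_rng(seed)
    n_mito = math.ceil(n_genes / 20)
    n_lnc = max(1, math.ceil(0.15 * n_genes))
    rows, seqs = [], {}
    for i in range(n_genes):
        if i < n_mito:
            gene_id, biotype, is_mito = f"mt-g{i:03d}", "protein_coding", True
        elif i < n_mito + n_lnc:
            gene_id, biotype, is_mito = f"lnc{i:03d}", "lncRNA", False
        else:
            gene_id, biotype, is_mito = f"g{i:03d}", "protein_coding", False
        length = int(rng.integers(min_len, min_len + 300))
        seqs[gene_id] = "".join(rng.choice(_BASES, size=length))
        rows.append((gene_id, length, biotype, is_mito))
    genes = pd.DataFrame(rows, columns=["gene_id", "length", "biotype", "is_mito"])
    txome = ToyTranscriptome(genes=genes, sequences=seqs)
    if out_dir is not None:
        txome.write(out_dir)
    return txome


# ---------------------------------------------------------------------------
# tDISCO run


@dataclass
class TdiscoTruth:
    """Per-read and per-cell ground truth of a simulated tDISCO run."""

    cell_zone: dict[str, str]
    cell_xy: dict[str, tuple[float, float]]
    program: pd.DataFrame  # genes x zones sampling weights
    read_truth: pd.DataFrame  # read_id, cell_id, gene_id, umi
    gene_groups: dict[str, list[str]]  # planted zone groups a-d
    seed: int


@dataclass
class TdiscoRun:
    """In-memory FASTQ trio plus metadata and truth for a simulated run."""

    r1: list[tuple[str, str, str]]
    i2: list[tuple[str, str, str]]
    r2: list[tuple[str, str, str]]
    cell_meta: pd.DataFrame
    truth: TdiscoTruth
    scheme: BarcodeScheme

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_fastq(out_dir / "R1.fastq.gz", self.r1)
        io.write_fastq(out_dir / "I2.fastq.gz", self.i2)
        io.write_fastq(out_dir / "R2.fastq.gz", self.r2)
        io.write_tsv(out_dir / "cell_meta.tsv", self.cell_meta)
        io.write_tsv(out_dir / "read_truth.tsv", self.truth.read_truth)
        io.write_json(
            out_dir / "truth.json",
            {
                "cell_zone": self.truth.cell_zone,
                "cell_xy": self.truth.cell_xy,
                "gene_groups": self.truth.gene_groups,
                "seed": self.truth.seed,
            },
        )
        io.write_json(out_dir / "scheme.json", self.scheme.to_dict())
        return out_dir


def _zone_program(
    txome: ToyTranscriptome, rng: np.random.Generator, n_per_group: int = 4
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-zone gene sampling weights with four planted localization groups.

    a: enriched in zone B (8x); b: silenced in B, expressed elsewhere;
    c: enriched in distal C/D (6x); d: lncRNA silenced in B. Group
    genes are drawn from the clearly expressed (above-median baseline)
    transcripts, mirroring the solidly detected grouped genes of the
    study's heatmap.
    """
    genes = txome.genes
    lnc = genes.loc[genes.biotype == "lncRNA", "gene_id"].tolist()
    coding = genes.loc[
        (genes.biotype == "protein_coding") & (~genes.is_mito), "gene_id"
    ].tolist()
    if len(coding) < 3 * n_per_group or len(lnc) < n_per_group:
        raise ConfigurationError("transcriptome too small to plant zone groups")
    base = rng.gamma(shape=2.0, scale=1.0, size=len(genes)) + 0.2
    baseline = pd.Series(base, index=genes.gene_id)
    coding_hi = [g for g in coding if baseline[g] >= baseline[coding].median()]
    lnc_hi = sorted(lnc, key=lambda g: -baseline[g])[: max(n_per_group, len(lnc) // 2)]
    if len(coding_hi) < 3 * n_per_group or len(lnc_hi) < n_per_group:
        raise ConfigurationError("too few well-expressed genes to plant zone groups")
    rng.shuffle(coding_hi)
    groups = {
        "a": coding_hi[:n_per_group],
        "b": coding_hi[n_per_group : 2 * n_per_group],
        "c": coding_hi[2 * n_per_group : 3 * n_per_group],
        "d": list(rng.choice(lnc_hi, size=n_per_group, replace=False)),
    }
    prog = pd.DataFrame(
        {z: base.copy() for z in ZONES}, index=genes.gene_id
    )
    prog.loc[groups["a"], "B"] *= 8.0
    prog.loc[groups["b"], "B"] = 0.0
    prog.loc[groups["c"], ["C", "D"]] *= 6.0
    prog.loc[groups["d"], "B"] = 0.0
    return prog, groups


def simulate_tdisco_run(
    scheme: BarcodeScheme,
    txome: ToyTranscriptome,
    cells_per_zone: int = 6,
    reads_per_cell: int = 500,
    umi_dup_rate: float = 0.3,
    bc_error_rate: float = 0.005,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_per_group: int = 4,
) -> TdiscoRun:
    """Simulate a tDISCO sequencing run over 4 zones with known truth.

    Each read draws its gene from the cell's zone program; with
    probability ``umi_dup_rate`` a read re-reads a previously emitted
    molecule of its cell (PCR duplicate), otherwise it starts a new
    molecule with a fresh UMI. Substitution errors hit the cell/SSS/
    index barcode segments at ``bc_error_rate`` per base; UMIs are left
    intact so molecule truth stays well defined.
    """
    n_cells = cells_per_zone * len(ZONES)
    if n_cells > scheme.capacity:
        raise ConfigurationError(
            f"{n_cells} cells exceed scheme capacity {scheme.capacity}"
        )
    rng = np.random.default_rng(seed)
    program, groups = _zone_program(txome, rng, n_per_group=n_per_group)
    gene_ids = program.index.to_numpy()
    seq_arr = {g: txome.sequences[g] for g in gene_ids}

    cells, cell_zone, cell_xy = [], {}, {}
    meta_rows = []
    for rank in range(n_cells):
        zone = ZONES[rank // cells_per_zone]
        triple = scheme.cell_tuple(rank)
        cell_id = ":".join(triple)
        lo, hi = ZONE_DISTANCE[zone]
        dist = float(rng.uniform(lo, hi))
        x, y = dist, float(rng.uniform(0, 2000.0))
        cells.append((cell_id, zone, triple))
        cell_zone[cell_id] = zone
        cell_xy[cell_id] = (x, y)
        meta_rows.append(
            (cell_id, zone, x, y, dist, "GFAP", f"animal{rank % 3 + 1}")
        )
    cell_meta = pd.DataFrame(
        meta_rows,
        columns=["cell_id", "zone", "x_um", "y_um", "distance_um", "stain", "animal_id"],
    )

    zone_probs = {
        z: (program[z] / program[z].sum()).to_numpy() for z in ZONES
    }
    umi_len = scheme.umi_len
    qual1 = "I" * 36
    qual2 = "I" * scheme.index2_len
    qual3 = "I" * scheme.read2_len
    spacer_len = 36 - (scheme.cell_segment[1] + umi_len + scheme.sss_segment[1])

    r1, i2, r2, truth_rows = [], [], [], []
    read_no = 0
    for cell_id, zone, (index_bc, sss_bc, cell_bc) in cells:
        probs = zone_probs[zone]
        molecules: list[tuple[str, str]] = []  # (gene, umi) per molecule
        for _ in range(reads_per_cell):
            if molecules and rng.random() < umi_dup_rate:
                gene, umi = molecules[rng.integers(len(molecules))]
            else:
                gene = gene_ids[rng.choice(len(gene_ids), p=probs)]
                umi = "".join(rng.choice(_BASES, size=umi_len))
                molecules.append((gene, umi))
            seq = seq_arr[gene]
            start = int(rng.integers(0, max(1, len(seq) - READ2_LEN + 1)))
            cdna = seq[start : start + READ2_LEN]
            if len(cdna) < READ2_LEN:  # pad short transcripts with low-complexity tail
                cdna = cdna + "A" * (READ2_LEN - len(cdna))
            spacer = "".join(rng.choice(_BASES, size=spacer_len))
            read1 = cell_bc + umi + sss_bc + spacer
            read1 = _inject_errors(
                read1,
                [(scheme.cell_segment), (scheme.sss_segment)],
                bc_error_rate,
                rng,
            )
            index_read = _inject_errors(
                index_bc, [(0, scheme.index2_len)], bc_error_rate, rng
            )
            name = f"read{read_no:07d}"
            r1.append((name, read1, qual1))
            i2.append((name, index_read, qual2))
            r2.append((name, cdna, qual3))
            truth_rows.append((name, cell_id, gene, umi))
            read_no += 1

    truth = TdiscoTruth(
        cell_zone=cell_zone,
        cell_xy=cell_xy,
        program=program,
        read_truth=pd.DataFrame(
            truth_rows, columns=["read_id", "cell_id", "gene_id", "umi"]
        ),
        gene_groups=groups,
        seed=seed,
    )
    run = TdiscoRun(r1=r1, i2=i2, r2=r2, cell_meta=cell_meta, truth=truth, scheme=scheme)
    if out_dir is not None:
        run.write(out_dir)
    return run


def _inject_errors(
    seq: str,
    segments: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for off, length in segments:
        hits = np.nonzero(rng.random(length) < rate)[0]
        for pos in hits:
            old = chars[off + pos]
            chars[off + pos] = rng.choice([b for b in "ACGT" if b != old])
    return "".join(chars)


# ---------------------------------------------------------------------------
# Visium-like section


@dataclass
class VisiumTruth:
    planted_w: np.ndarray  # spots x k_true loadings
    injury_factor: int
    injury_spots: list[str]
    marker_genes: dict[int, list[str]]
    seed: int


def hex_lattice(n_rows: int, n_cols: int, spacing_um: float = 100.0) -> pd.DataFrame:
    """Offset hexagonal lattice: odd rows shifted half a spacing in x."""
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            x = c * spacing_um + (r % 2) * spacing_um / 2.0
            y = r * spacing_um * math.sqrt(3) / 2.0
            rows.append((f"spot_{r:02d}_{c:02d}", r, c, x, y))
    return pd.DataFrame(rows, columns=["spot_id", "array_row", "array_col", "x_um", "y_um"])


def simulate_visium_section(
    n_rows: int = 20,
    n_cols: int = 20,
    n_genes: int = 90,
    k_true: int = 3,
    injury_center: tuple[int, int] | None = None,
    injury_radius: int = 3,
    seed: int = 0,
    phi: float = 0.2,
    spacing_um: float = 100.0,
    depth: float = 30.0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, VisiumTruth]:
    """Hex-lattice spot counts with a planted, disc-confined injury factor.

    Factor 0 ('injury') has loadings supported ONLY on the disc of
    ``injury_radius`` lattice spacings around ``injury_center``
    (default: lattice centre). Remaining factors are smooth non-negative
    spatial fields. Counts are negative binomial around W·H with
    dispersion ``phi``. Returns (counts genes x spots, coordinates,
    truth).
    """
    if k_true < 2:
        raise ConfigurationError("k_true must be >= 2")
    rng = np.random.default_rng(seed)
    coords = hex_lattice(n_rows, n_cols, spacing_um)
    n_spots = len(coords)
    if injury_center is None:
        injury_center = (n_rows // 2, n_cols // 2)
    cx = coords.loc[
        (coords.array_row == injury_center[0]) & (coords.array_col == injury_center[1])
    ]
    if cx.empty:
        raise ConfigurationError(f"injury_center {injury_center} outside lattice")
    cx, cy = float(cx.x_um.iloc[0]), float(cx.y_um.iloc[0])
    d = np.hypot(coords.x_um - cx, coords.y_um - cy).to_numpy()
    disc = d <= injury_radius * spacing_um + 1e-6
    if not disc.any():
        raise ConfigurationError("injury disc contains no spots")

    w = np.zeros((n_spots, k_true))
    w[disc, 0] = np.exp(-(d[disc] ** 2) / (2 * (injury_radius * spacing_um / 1.5 + 1) ** 2))
    xs = coords.x_um.to_numpy()
    ys = coords.y_um.to_numpy()
    span_x = xs.max() - xs.min() + 1e-9
    span_y = ys.max() - ys.min() + 1e-9
    for f in range(1, k_true):
        # smooth ramps in alternating directions, zeroed on the injury disc
        # so the planted factors have near-disjoint spatial support
        t = (xs - xs.min()) / span_x if f % 2 == 1 else (ys - ys.min()) / span_y
        ramp = t if f < 3 else 1.0 - t
        w[:, f] = np.clip(ramp - 0.15, 0.0, None) ** 2
        w[disc, f] = 0.0

    genes = [f"g{j:03d}" for j in range(n_genes)]
    h = rng.gamma(shape=0.5, scale=0.4, size=(k_true, n_genes))
    block = n_genes // (k_true + 1)
    markers: dict[int, list[str]] = {}
    for f in range(k_true):
        cols = slice(f * block, (f + 1) * block)
        h[f, cols] += rng.gamma(shape=8.0, scale=1.0, size=block)
        markers[f] = genes[f * block : (f + 1) * block]

    mean = depth * (w @ h) + 0.05
    counts = rng.poisson(rng.gamma(shape=1.0 / phi, scale=mean * phi))
    counts_df = pd.DataFrame(counts.T, index=genes, columns=coords.spot_id)
    counts_df.index.name = "gene_id"
    truth = VisiumTruth(
        planted_w=w,
        injury_factor=0,
        injury_spots=coords.spot_id[disc].tolist(),
        marker_genes=markers,
        seed=seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        gene_meta = pd.DataFrame({"gene_id": genes})
        io.write_mtx(out_dir, counts_df.to_numpy(), gene_meta, list(counts_df.columns))
        io.write_tsv(out_dir / "coords.tsv", coords)
        io.write_json(
            out_dir / "truth.json",
            {
                "injury_factor": truth.injury_factor,
                "injury_spots": truth.injury_spots,
                "marker_genes": {str(k): v for k, v in markers.items()},
                "seed": seed,
            },
        )
    return counts_df, coords, truth


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass
class ScTruth:
    cluster: pd.Series  # cell -> true cluster
    condition: pd.Series  # cell -> injured | uninjured
    programs: pd.DataFrame  # genes x clusters mean expression
    marker_genes: dict[str, list[str]]
    seed: int


def default_cluster_programs(
    n_genes: int = 60, n_clusters: int = 3, marker_mean: float = 6.0, base_mean: float = 0.5
) -> pd.DataFrame:
    """Cluster programs with disjoint marker blocks of n_genes // (n_clusters+1)."""
    genes = [f"g{j:03d}" for j in range(n_genes)]
    prog = pd.DataFrame(base_mean, index=genes, columns=[f"c{i}" for i in range(n_clusters)])
    block = n_genes // (n_clusters + 1)
    for i in range(n_clusters):
        prog.iloc[i * block : (i + 1) * block, i] = marker_mean
    return prog


def simulate_sc_counts(
    n_cells_per_condition: int = 150,
    cluster_programs: pd.DataFrame | None = None,
    injured_fraction: dict[str, float] | None = None,
    phi: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, ScTruth]:
    """NB single-cell counts from cluster programs with condition labels.

    ``injured_fraction`` gives the probability that a cell of each
    cluster comes from the injured condition (default: one strongly
    injury-enriched cluster at 0.9, the rest balanced at 0.5).
    """
    rng = np.random.default_rng(seed)
    if cluster_programs is None:
        cluster_programs = default_cluster_programs()
    if (cluster_programs < 0).to_numpy().any():
        raise ConfigurationError("cluster programs must be non-negative")
    clusters = list(cluster_programs.columns)
    if len(clusters) < 2:
        raise ConfigurationError("need >= 2 clusters")
    if injured_fraction is None:
        injured_fraction = {c: 0.5 for c in clusters}
        injured_fraction[clusters[1]] = 0.9
    n_total = 2 * n_cells_per_condition
    cluster_of = rng.choice(clusters, size=n_total)
    condition = np.array(
        [
            "injured" if rng.random() < injured_fraction[c] else "uninjured"
            for c in cluster_of
        ]
    )
    means = cluster_programs[cluster_of].to_numpy()  # genes x cells
    counts = rng.poisson(rng.gamma(shape=1.0 / phi, scale=means * phi))
    cell_ids = [f"cell{i:04d}" for i in range(n_total)]
    counts_df = pd.DataFrame(counts, index=cluster_programs.index, columns=cell_ids)
    counts_df.index.name = "gene_id"
    block = len(cluster_programs) // (len(clusters) + 1)
    markers = {
        c: cluster_programs.index[i * block : (i + 1) * block].tolist()
        for i, c in enumerate(clusters)
    }
    truth = ScTruth(
        cluster=pd.Series(cluster_of, index=cell_ids, name="cluster"),
        condition=pd.Series(condition, index=cell_ids, name="condition"),
        programs=cluster_programs,
        marker_genes=markers,
        seed=seed,
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# LFQ proteomics


@dataclass
class LfqTruth:
    de_proteins: list[str]
    effects: pd.Series  # protein -> planted log2 effect (zone B minus zone D)
    seed: int


def simulate_lfq_table(
    n_proteins: int = 300,
    n_per_zone: int = 5,
    effect_lfc: float = 2.0,
    frac_de: float = 0.1,
    missing_shift: float = 1.8,
    seed: int = 0,
    noise_sd: float = 0.5,
    zone_shift: float = -1.0,
    censor_width: float = 0.4,
    censor_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.Series, LfqTruth]:
    """log2 LFQ intensities for zone B vs zone D with MNAR missingness.

    Zone-B samples are globally shifted by ``zone_shift`` log2 units
    (default -1), so left-censoring removes more zone-B values — the
    'fewer proteins detected in zone B' asymmetry. Missingness is
    probit left-censoring: P(missing | x) = Phi((c - x) / width), with
    c = global mean - missing_shift * global sd unless
    ``censor_threshold`` overrides it (``-inf`` disables missingness).
    Returns (table proteins x samples with NaN for missing, sample->zone
    map, truth).
    """
    if n_per_zone < 3:
        raise ConfigurationError("n_per_zone must be >= 3")
    rng = np.random.default_rng(seed)
    proteins = [f"P{j:04d}" for j in range(n_proteins)]
    samples = [f"B{i+1}" for i in range(n_per_zone)] + [
        f"D{i+1}" for i in range(n_per_zone)
    ]
    zone = pd.Series(["B"] * n_per_zone + ["D"] * n_per_zone, index=samples, name="zone")

    base = rng.normal(25.0, 2.0, size=n_proteins)
    n_de = int(round(frac_de * n_proteins)) if effect_lfc != 0 else 0
    de_idx = rng.choice(n_proteins, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(n_proteins)
    effect[de_idx] = signs * effect_lfc

    mean = np.tile(base[:, None], (1, 2 * n_per_zone)).astype(float)
    mean[:, :n_per_zone] += effect[:, None] + zone_shift
    x = mean + rng.normal(0.0, noise_sd, size=mean.shape)

    if censor_threshold is None:
        c = x.mean() - missing_shift * x.std()
    else:
        c = censor_threshold
    if np.isfinite(c):
        width = max(censor_width * x.std(), 1e-9)
        p_miss = scipy.stats.norm.cdf((c - x) / width)
        x = np.where(rng.random(x.shape) < p_miss, np.nan, x)

    table = pd.DataFrame(x, index=proteins, columns=samples)
    table.index.name = "protein_id"
    truth = LfqTruth(
        de_proteins=[proteins[i] for i in de_idx],
        effects=pd.Series(effect, index=proteins, name="log2_effect"),
        seed=seed,
    )
    return table, zone, truth
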