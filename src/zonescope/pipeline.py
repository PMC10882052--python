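"""End-to-end synthetic pipeline: simulate -> demux -> QC -> spatial ->
map -> zone DE -> protein DE, with a structured recovery report.

The default configuration runs everything at desk scale (tens of cells,
a 20x20 spot lattice, ~60-90 genes) in well under a minute while still
exercising every stage against its recorded ground truth. A single
global seed fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, mapcells, protde, qc, reads, spatial, syndata, zonede
from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Study-quoted analysis constants (QC thresholds, marker criteria,
    NMF k = 20, FDR 0.05, proteomics alpha = 0.05 / lfc = 1, zone edges
    0/200/400/600 µm) keep their quoted defaults in the corresponding
    modules; the desk-scale values here size the synthetic run.
    """

    seed: int = 0
    # synthetic sizes
    n_genes_txome: int = 60
    min_transcript_len: int = 300
    cells_per_zone: int = 5
    reads_per_cell: int = 400
    umi_dup_rate: float = 0.3
    bc_error_rate: float = 0.005
    visium_rows: int = 20
    visium_cols: int = 20
    visium_genes: int = 90
    k_true: int = 3
    injury_radius: int = 3
    sc_cells_per_condition: int = 150
    n_proteins: int = 300
    lfq_per_zone: int = 5
    lfq_effect: float = 2.0
    lfq_frac_de: float = 0.1
    # analysis parameters
    max_mismatch: int = 1
    kmer: int = 21
    nmf_k: int = 3
    n_spot_clusters: int = 3
    fdr: float = 0.05
    prot_alpha: float = 0.05
    prot_lfc: float = 1.0
    zone_edges: tuple[float, ...] = (0.0, 200.0, 400.0, 600.0)
    distal_threshold: float = 1000.0
    # desk-scale QC (the study-scale thresholds live in qc.QcThresholds defaults)
    qc_min_genes: int = 5
    qc_max_genes: int = 10_000
    qc_max_mito: float = 0.30
    qc_spot_min_genes: int = 20
    qc_gene_min_spots: int = 5

    def qc_thresholds(self) -> qc.QcThresholds:
        return qc.QcThresholds(
            min_genes_cell=self.qc_min_genes,
            max_genes_cell=self.qc_max_genes,
            max_mito_frac=self.qc_max_mito,
            min_gene_count_spot=self.qc_spot_min_genes,
            min_gene_spots=self.qc_gene_min_spots,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_edges"] = list(self.zone_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["zone_edges"] = tuple(d.get("zone_edges", (0.0, 200.0, 400.0, 600.0)))
        return cls(**d)


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic fan-out of one global seed into per-stage seeds (< 2^31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_tdisco_stage(config: PipelineConfig, seed: int) -> dict:
    """Simulate a tDISCO run, demultiplex, count, TPM-normalize, and run
    the zone NB-LRT; returns data and truth-recovery metrics."""
    txome = syndata.make_toy_transcriptome(
        config.n_genes_txome, config.min_transcript_len, seed=seed
    )
    scheme = reads.BarcodeScheme.default(n_cells=config.cells_per_zone * 4)
    run = syndata.simulate_tdisco_run(
        scheme,
        txome,
        cells_per_zone=config.cells_per_zone,
        reads_per_cell=config.reads_per_cell,
        umi_dup_rate=config.umi_dup_rate,
        bc_error_rate=config.bc_error_rate,
        seed=seed + 1,
    )
    assigned, log = reads.demultiplex(run.r1, run.i2, run.r2, scheme, config.max_mismatch)
    truth_by_read = run.truth.read_truth.set_index("read_id")
    correct = (
        assigned["cell_id"].to_numpy()
        == truth_by_read.loc[assigned["read_id"], "cell_id"].to_numpy()
    )
    index = reads.build_kmer_index(txome.sequences, k=config.kmer)
    genes_assigned = [reads.assign_transcript(r2, index) for r2 in assigned["read2"]]
    keep = [
        g not in (reads.MULTI, reads.NONE) for g in genes_assigned
    ]
    molecules = [
        (c, g, u)
        for c, g, u, k in zip(
            assigned["cell_id"], genes_assigned, assigned["umi"], keep
        )
        if k
    ]
    _, counts = reads.collapse_umis(molecules)
    counts = counts.reindex(
        index=txome.genes.gene_id, columns=run.cell_meta.cell_id, fill_value=0
    )
    tpm = reads.tpm_normalize(counts, txome.lengths)
    meta = reads.attach_metadata(
        counts, run.cell_meta, config.zone_edges, config.distal_threshold
    )
    zones = meta.set_index("cell_id")["zone"]
    fit = zonede.estimate_dispersion(counts, zones)
    de = zonede.nb_lrt(counts, zones, fit)
    zone_means = pd.DataFrame(
        {z: tpm.loc[:, (zones == z).to_numpy()].mean(axis=1) for z in "ABCD"}
    )
    groups = zonede.classify_zone_groups(
        de, zone_means, txome.genes.set_index("gene_id")["biotype"], fdr=config.fdr
    )
    planted = run.truth.gene_groups
    recovered = {
        g: sorted(set(groups[groups == g].index) & set(planted[g]))
        for g in "abcd"
    }
    return {
        "txome": txome,
        "run": run,
        "counts": counts,
        "tpm": tpm,
        "zones": zones,
        "de": de,
        "zone_groups": groups,
        "metrics": {
            "reads_total": log["total"],
            "reads_assigned": log["assigned"],
            "assigned_fraction": log["assigned"] / max(log["total"], 1),
            "cell_assignment_accuracy": float(np.mean(correct)) if len(correct) else 0.0,
            "n_molecules": int(counts.to_numpy().sum()),
            "planted_groups_recovered": {
                g: len(recovered[g]) / len(planted[g]) for g in "abcd"
            },
        },
    }


def run_visium_stage(config: PipelineConfig, seed: int) -> dict:
    """Simulate a Visium-like section; spot QC, residual normalization,
    NMF, Moran autocorrelation, injury-factor pick, border DE."""
    counts, coords, truth = syndata.simulate_visium_section(
        config.visium_rows,
        config.visium_cols,
        config.visium_genes,
        k_true=config.k_true,
        injury_radius=config.injury_radius,
        seed=seed,
    )
    filtered = qc.filter_spots(counts, config.qc_thresholds())
    kept_coords = coords[coords.spot_id.isin(filtered.columns)].reset_index(drop=True)
    lattice = spatial.build_adjacency(kept_coords)
    normalized = qc.pearson_residual_normalize(filtered)
    model = spatial.nmf(filtered.clip(lower=0), k=config.nmf_k, seed=seed)
    injury_region = set(truth.injury_spots) & set(filtered.columns)
    injury_factor = spatial.pick_injury_factor(model, injury_region)
    morans = [
        spatial.global_moran(model.w[:, f], lattice) for f in range(model.k)
    ]
    labels = spatial.cluster_spots(model, config.n_spot_clusters, seed=seed)
    injury_cluster = int(
        pd.Series(labels[np.isin(model.spot_ids, list(injury_region))]).mode()[0]
    )
    border = spatial.region_neighbors(labels, injury_cluster, lattice)
    injury_spots_lab = set(np.array(model.spot_ids)[labels == injury_cluster])
    de = spatial.de_injury_vs_border(normalized, injury_spots_lab, border)
    top = spatial.top_factor_genes(model, injury_factor, n=10)
    planted_markers = set(truth.marker_genes[truth.injury_factor])
    return {
        "counts": filtered,
        "lattice": lattice,
        "normalized": normalized,
        "model": model,
        "labels": labels,
        "border": border,
        "de": de,
        "truth": truth,
        "metrics": {
            "n_spots_kept": int(filtered.shape[1]),
            "injury_factor": injury_factor,
            "injury_factor_moran": morans[injury_factor],
            "factor_morans": morans,
            "n_border_spots": len(border),
            "injury_marker_top10_overlap": len(set(top) & planted_markers) / 10.0,
        },
    }


def run_sc_stage(config: PipelineConfig, seed: int, visium: dict | None = None) -> dict:
    """Simulate single-cell counts; QC, clustering, markers, condition
    proportions, and transfer onto the Visium section when provided."""
    counts, truth = syndata.simulate_sc_counts(
        config.sc_cells_per_condition, seed=seed
    )
    gene_meta = pd.DataFrame(
        {"gene_id": counts.index, "is_mito": False}
    )
    with warnings.catch_warnings():
        # the toy single-cell transcriptome carries no mito genes by design
        warnings.filterwarnings("ignore", message="no mitochondrial genes")
        filtered, qc_report = qc.filter_cells(counts, gene_meta, config.qc_thresholds())
    normalized = qc.lognormalize(filtered)
    labels = mapcells.cluster_cells(normalized, n_pcs=10, seed=seed)
    markers = mapcells.find_markers(normalized, labels)
    props = mapcells.proportion_by_condition(labels, truth.condition.loc[labels.index])
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(truth.cluster.loc[labels.index], labels)
    result = {
        "counts": filtered,
        "normalized": normalized,
        "labels": labels,
        "markers": markers,
        "proportions": props,
        "truth": truth,
        "metrics": {
            "qc": qc_report,
            "n_clusters": int(labels.nunique()),
            "cluster_ari": float(ari),
            "n_marker_genes": int(sum(len(m) for m in markers.values())),
        },
    }
    if visium is not None:
        scores = mapcells.transfer_scores(
            normalized, labels, qc.lognormalize(visium["counts"]), n_features=40
        )
        overlay = mapcells.overlay_scores(scores, visium["lattice"])
        result["scores"] = scores
        result["overlay"] = overlay
        result["metrics"]["score_rowsum_max_dev"] = float(
            np.abs(scores.sum(axis=1) - 1.0).max()
        )
    return result


def run_prot_stage(config: PipelineConfig, seed: int) -> dict:
    """Simulate an LFQ table; filter, impute, moderated t-test."""
    table, zones, truth = syndata.simulate_lfq_table(
        config.n_proteins,
        config.lfq_per_zone,
        effect_lfc=config.lfq_effect,
        frac_de=config.lfq_frac_de,
        seed=seed,
    )
    filtered = protde.filter_proteins(table, zones)
    normalized = protde.normalize_intensities(filtered)
    imputed = protde.impute_missing(normalized, seed=seed)
    group_b = zones[zones == "B"].index.tolist()
    group_d = zones[zones == "D"].index.tolist()
    de = protde.moderated_ttest(
        imputed, group_b, group_d, alpha=config.prot_alpha, lfc=config.prot_lfc
    )
    called = set(de.loc[de.significant, "protein_id"])
    true_de = set(truth.de_proteins) & set(filtered.index)
    tp = len(called & set(truth.de_proteins))
    return {
        "table": filtered,
        "de": de,
        "truth": truth,
        "metrics": {
            "n_proteins_kept": int(filtered.shape[0]),
            "n_significant": len(called),
            "recall": tp / max(len(true_de), 1),
            "false_discovery_rate": (len(called) - tp) / max(len(called), 1),
        },
    }


def run_all(config: PipelineConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run every stage on synthetic data and return the recovery report."""
    config = config or PipelineConfig()
    seeds = stage_seeds(config.seed)
    report = {"config": config.to_dict(), "stages": {}}
    tdisco = run_tdisco_stage(config, seeds[0])
    report["stages"]["tdisco"] = tdisco["metrics"]
    visium = run_visium_stage(config, seeds[1])
    report["stages"]["visium"] = visium["metrics"]
    sc = run_sc_stage(config, seeds[2], visium=visium)
    report["stages"]["single_cell"] = sc["metrics"]
    prot = run_prot_stage(config, seeds[3])
    report["stages"]["proteomics"] = prot["metrics"]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_json(out_dir / "report.json", report)
        io.write_tsv(out_dir / "tdisco_de.tsv", tdisco["de"])
        io.write_tsv(out_dir / "visium_de.tsv", visium["de"])
        io.write_tsv(out_dir / "protein_de.tsv", prot["de"])
    return report
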