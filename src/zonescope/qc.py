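"""Quality-control filters and normalizations for cell and spot matrices.

Thresholds follow the study defaults: cells are removed when they have
fewer than 200 detected genes, more than 3800 detected genes (doublet
proxy), or more than 30% mitochondrial counts; Visium spots need at
least 100 detected genes and genes must appear in at least 5 spots.
Boundary semantics are strict inequalities ("more than" / "less than").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class QcThresholds:
    min_genes_cell: int = 200
    max_genes_cell: int = 3800
    max_mito_frac: float = 0.30
    min_gene_count_spot: int = 100
    min_gene_spots: int = 5

    def __post_init__(self) -> None:
        if self.min_genes_cell >= self.max_genes_cell:
            raise InputError("min_genes_cell must be < max_genes_cell")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise InputError("max_mito_frac must lie in [0, 1]")


def filter_cells(
    counts: pd.DataFrame,
    gene_meta: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Drop cells failing the detected-gene and mitochondrial-fraction rules.

    A cell is removed when genes < min (strictly fewer than 200
    detected), genes > max (strictly more than 3800), or mitochondrial
    count fraction > 30%. The report gives per-criterion removal counts
    (a cell can trip several) and the overlap.
    """
    t = thresholds or QcThresholds()
    detected = (counts > 0).sum(axis=0)
    mito_genes = gene_meta.loc[gene_meta["is_mito"].astype(bool), "gene_id"]
    mito_genes = counts.index.intersection(mito_genes)
    total = counts.sum(axis=0).astype(float)
    if len(mito_genes) == 0:
        warnings.warn(
            "no mitochondrial genes flagged; mito criterion skipped", stacklevel=2
        )
        mito_frac = pd.Series(0.0, index=counts.columns)
        mito_skipped = True
    else:
        with np.errstate(invalid="ignore"):
            mito_frac = counts.loc[mito_genes].sum(axis=0) / total.replace(0, np.nan)
        mito_frac = mito_frac.fillna(0.0)
        mito_skipped = False
    low = detected < t.min_genes_cell
    high = detected > t.max_genes_cell
    mito = mito_frac > t.max_mito_frac
    removed = low | high | mito
    report = {
        "n_input": int(counts.shape[1]),
        "n_kept": int((~removed).sum()),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_mito": int(mito.sum()),
        "removed_total": int(removed.sum()),
        "removed_overlap": int((low.astype(int) + high.astype(int) + mito.astype(int) > 1).sum()),
        "mito_criterion_skipped": mito_skipped,
    }
    return counts.loc[:, ~removed], report


def filter_spots(
    counts: pd.DataFrame, thresholds: QcThresholds | None = None
) -> pd.DataFrame:
    """Visium spot/gene filter: spots need >= 100 detected genes; genes
    must be detected in >= 5 spots (gene filter applied after the spot
    filter)."""
    t = thresholds or QcThresholds()
    detected_per_spot = (counts > 0).sum(axis=0)
    kept = counts.loc[:, detected_per_spot >= t.min_gene_count_spot]
    spots_per_gene = (kept > 0).sum(axis=1)
    kept = kept.loc[spots_per_gene >= t.min_gene_spots]
    if kept.empty:
        raise InputError(
            "no spots or genes survive filtering; review min_gene_count_spot / min_gene_spots"
        )
    return kept


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Seurat-style log-normalization: x -> ln(1 + scale * x / colsum)."""
    colsum = counts.sum(axis=0).astype(float)
    zero = colsum == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-sum columns left as zeros", stacklevel=2)
        colsum = colsum.replace(0, 1.0)
    return np.log1p(counts.div(colsum, axis=1) * scale)


def pearson_residual_normalize(counts: pd.DataFrame, theta: float = 100.0) -> pd.DataFrame:
    """Analytic Pearson residuals under a NB null with fixed dispersion.

    mu_gc = rowsum_g * colsum_c / total; r = (x - mu) / sqrt(mu +
    mu^2/theta), clipped to +/- sqrt(n_cells). A variance-stabilizing
    stand-in for regularized NB regression.
    """
    if theta <= 0:
        raise InputError("theta must be > 0")
    x = counts.to_numpy(dtype=float)
    total = x.sum()
    if total == 0:
        raise InputError("all-zero matrix cannot be normalized")
    mu = np.outer(x.sum(axis=1), x.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x - mu) / np.sqrt(mu + mu**2 / theta)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    clip = np.sqrt(counts.shape[1])
    return pd.DataFrame(
        np.clip(r, -clip, clip), index=counts.index, columns=counts.columns
    )


def astro_subset(
    normalized: pd.DataFrame,
    genes: tuple[str, str] = ("Aif1", "Trem2"),
    cutoff: float = 0.1,
) -> list[str]:
    """Cells where BOTH microglial markers fall below the normalized cutoff.

    Mirrors the study's delineation of astrocyte-like cells as those
    with Aif1 and Trem2 below a normalized expression of 0.1.
    """
    missing = [g for g in genes if g not in normalized.index]
    if missing:
        raise InputError(f"genes absent from matrix: {missing}")
    mask = (normalized.loc[list(genes)] < cutoff).all(axis=0)
    return normalized.columns[mask].tolist()
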