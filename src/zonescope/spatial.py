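"""Hex-lattice spatial analysis of Visium-like sections.

Covers the spatial arm of the study: non-negative matrix factorization
of the spot-by-gene matrix into additive spatial factors (default 20),
global and per-spot Moran's I spatial autocorrelation of factor
loadings, selection of the factor localized to the injury site,
k-means clustering of spots on factor loadings, detection of the spots
bordering a cluster, and rank-sum differential expression between an
injured cluster and its border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigurationError, InputError
from .zonede import bh_adjust


@dataclass
class SpotLattice:
    """Spot coordinates plus a symmetric, irreflexive adjacency relation."""

    coords: pd.DataFrame  # spot_id, array_row, array_col, x_um, y_um
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal

    @property
    def spot_ids(self) -> list[str]:
        return self.coords["spot_id"].tolist()

    def neighbors(self, spot_id: str) -> list[str]:
        i = self.coords.index[self.coords.spot_id == spot_id][0]
        ids = self.coords["spot_id"].to_numpy()
        return ids[self.adjacency[i].indices].tolist()


def build_adjacency(coords: pd.DataFrame, spacing_factor: float = 1.2) -> SpotLattice:
    """Connect spots closer than spacing_factor x the minimum pairwise distance.

    On a hexagonal lattice this yields the 6-neighborhood for interior
    spots and 2-4 neighbors at edges and corners.
    """
    if len(coords) < 2:
        raise InputError("need >= 2 spots to build adjacency")
    xy = coords[["x_um", "y_um"]].to_numpy(dtype=float)
    d = squareform(pdist(xy))
    off_diag = d[~np.eye(len(d), dtype=bool)]
    if (off_diag == 0).any():
        raise InputError("duplicate spot coordinates")
    cutoff = spacing_factor * off_diag.min()
    adj = (d <= cutoff) & ~np.eye(len(d), dtype=bool)
    return SpotLattice(coords=coords.reset_index(drop=True), adjacency=sp.csr_matrix(adj.astype(np.int8)))


@dataclass
class FactorModel:
    """Non-negative factorization: spots x k loadings W, k x genes weights H."""

    w: np.ndarray
    h: np.ndarray
    loss_trace: list[float]
    spot_ids: list[str]
    gene_ids: list[str]

    @property
    def k(self) -> int:
        return self.w.shape[1]


def nmf(
    matrix: pd.DataFrame,
    k: int = 20,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> FactorModel:
    """Multiplicative-update NMF of a genes x spots matrix (Frobenius loss).

    W (spots x k) and H (k x genes) are initialized from a seeded
    uniform draw scaled to the data; updates stop when the relative loss
    improvement drops below ``tol`` or after ``max_iter`` sweeps. The
    per-iteration loss trace is recorded and is non-increasing.
    """
    x = matrix.to_numpy(dtype=float).T  # spots x genes
    if (x < 0).any():
        raise InputError("NMF requires a non-negative matrix")
    n, m = x.shape
    if k >= min(n, m):
        raise ConfigurationError(f"k={k} must be < min(n_spots, n_genes)={min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(x.mean() / k) + 1e-12
    w = rng.uniform(1e-4, 1.0, size=(n, k)) * scale
    h = rng.uniform(1e-4, 1.0, size=(k, m)) * scale
    eps = 1e-12
    loss = [float(np.linalg.norm(x - w @ h, "fro") ** 2)]
    for _ in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + eps)
        w *= (x @ h.T) / (w @ (h @ h.T) + eps)
        loss.append(float(np.linalg.norm(x - w @ h, "fro") ** 2))
        if loss[-2] - loss[-1] < tol * max(loss[-2], eps):
            break
    return FactorModel(
        w=w, h=h, loss_trace=loss,
        spot_ids=list(matrix.columns), gene_ids=list(matrix.index),
    )


def global_moran(values: np.ndarray, lattice: SpotLattice) -> float:
    """Global Moran's I with binary weights:
    I = (n / sum w) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = (z**2).sum()
    if len(z) < 3 or denom == 0:
        warnings.warn("constant or tiny input; Moran's I set to 0", stacklevel=2)
        return 0.0
    w = lattice.adjacency
    s0 = w.sum()
    return float(len(z) / s0 * (z @ (w @ z)) / denom)


def local_autocorrelation(values: np.ndarray, lattice: SpotLattice) -> np.ndarray:
    """Per-spot local Moran's I: I_i = n * z_i * sum_j w_ij z_j / sum z^2."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = (z**2).sum()
    if len(z) < 3 or denom == 0:
        warnings.warn("constant or tiny input; local Moran set to 0", stacklevel=2)
        return np.zeros(len(z))
    lag = lattice.adjacency @ z
    return len(z) * z * lag / denom


def spatial_lag(values: np.ndarray, lattice: SpotLattice) -> np.ndarray:
    """Neighbor-mean smoothed values (row-standardized lag), the other
    plausible reading of a per-spot 'spatial autocorrelation value'."""
    w = lattice.adjacency
    deg = np.asarray(w.sum(axis=1)).ravel()
    deg[deg == 0] = 1
    return (w @ np.asarray(values, dtype=float)) / deg


def localize_factor(
    model: FactorModel, region: set[str], eps: float = 1e-9
) -> np.ndarray:
    """Per-factor enrichment: mean loading inside region / (outside + eps)."""
    ids = np.array(model.spot_ids)
    inside = np.isin(ids, list(region))
    if not inside.any() or inside.all():
        raise InputError("region must be a nonempty strict subset of spots")
    return model.w[inside].mean(axis=0) / (model.w[~inside].mean(axis=0) + eps)


def pick_injury_factor(model: FactorModel, region: set[str]) -> int:
    """Index of the factor most enriched on the injury region."""
    return int(np.argmax(localize_factor(model, region)))


def top_factor_genes(model: FactorModel, factor: int, n: int = 10) -> list[str]:
    """Genes ranked by H weight for one factor (descending; ties by id)."""
    if n > len(model.gene_ids):
        raise InputError("n exceeds number of genes")
    order = sorted(
        range(len(model.gene_ids)),
        key=lambda j: (-model.h[factor, j], model.gene_ids[j]),
    )
    return [model.gene_ids[j] for j in order[:n]]


def cluster_spots(
    loadings: np.ndarray | FactorModel, n_clusters: int, seed: int = 0
) -> np.ndarray:
    """Seeded k-means over NMF loadings (or any per-spot embedding)."""
    x = loadings.w if isinstance(loadings, FactorModel) else np.asarray(loadings)
    if n_clusters < 2:
        raise ConfigurationError("n_clusters must be >= 2")
    if n_clusters > x.shape[0]:
        raise InputError("more clusters than spots")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(x)


def region_neighbors(
    labels: np.ndarray, target_cluster: int, lattice: SpotLattice
) -> set[str]:
    """Spots outside ``target_cluster`` adjacent to at least one spot in it."""
    labels = np.asarray(labels)
    in_target = labels == target_cluster
    if not in_target.any():
        raise InputError("target cluster is empty")
    touch = np.asarray((lattice.adjacency @ in_target.astype(int)) > 0)
    border = touch & ~in_target
    ids = np.array(lattice.spot_ids)
    return set(ids[border])


def de_injury_vs_border(
    normalized: pd.DataFrame, injury_spots: set[str], border_spots: set[str]
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum between injury and border spots.

    Returns a DEResult table (gene_id, mean_injury, mean_border, lfc
    [log2 of mean ratio], stat, pvalue, padj) sorted by p-value.
    """
    if len(injury_spots) < 3 or len(border_spots) < 3:
        raise InputError("need >= 3 spots in each group")
    a = normalized[list(injury_spots)].to_numpy(dtype=float)
    b = normalized[list(border_spots)].to_numpy(dtype=float)
    stat, p = scipy.stats.ranksums(a, b, axis=1)
    constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (
        a.mean(axis=1) == b.mean(axis=1)
    )
    p = np.where(constant, 1.0, p)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # log ratio is only meaningful for non-negative normalizations; residual
    # inputs (negative means) get NaN there and mean_diff carries the effect
    both_pos = (mean_a > -1e-9) & (mean_b > -1e-9)
    lfc = np.full(len(mean_a), np.nan)
    lfc[both_pos] = np.log2(
        (np.clip(mean_a[both_pos], 0, None) + 1e-9)
        / (np.clip(mean_b[both_pos], 0, None) + 1e-9)
    )
    out = pd.DataFrame(
        {
            "gene_id": normalized.index,
            "mean_injury": mean_a,
            "mean_border": mean_b,
            "mean_diff": mean_a - mean_b,
            "lfc": lfc,
            "stat": stat,
            "pvalue": p,
            "padj": bh_adjust(p),
        }
    )
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
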