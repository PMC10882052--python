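"""Single-cell clustering, marker detection, and cluster-to-spot transfer.

Cells are clustered by PCA, a k-nearest-neighbor graph and greedy
modularity community detection. Cluster markers follow the study's
criteria: one-vs-rest Wilcoxon with >0.25 natural-log fold change,
detection in >25% of in-cluster cells, and adjusted p < 0.05. Cluster
labels are transferred onto spatial spots by non-negative least-squares
projection of each spot profile on cluster centroids over shared
variable features; the normalized coefficients play the role of
probabilistic prediction scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import networkx as nx
from scipy.optimize import nnls
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import InputError
from .zonede import bh_adjust


@dataclass
class MarkerCriteria:
    """Marker-gene thresholds: ln-fold change, in-cluster detection rate, FDR."""

    min_lfc: float = 0.25
    min_pct: float = 0.25
    max_adj_p: float = 0.05

    def __post_init__(self) -> None:
        if not (self.min_lfc > 0 and 0 < self.min_pct < 1 and self.max_adj_p > 0):
            raise InputError("invalid marker criteria")


def cluster_cells(
    normalized: pd.DataFrame,
    n_pcs: int = 10,
    n_neighbors: int = 10,
    seed: int = 0,
) -> pd.Series:
    """PCA -> kNN graph -> greedy modularity communities.

    Deterministic for a fixed seed. Singleton communities are merged
    into the cluster with the nearest centroid (warned)."""
    x = normalized.to_numpy(dtype=float).T  # cells x genes
    n_cells = x.shape[0]
    if n_cells <= n_neighbors:
        raise InputError(f"{n_cells} cells but n_neighbors={n_neighbors}")
    if n_cells <= n_pcs:
        raise InputError("need more cells than principal components")
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    g.add_edges_from((i, j) for i in range(n_cells) for j in idx[i, 1:])
    communities = nx.algorithms.community.greedy_modularity_communities(g)
    labels = np.empty(n_cells, dtype=int)
    for c, members in enumerate(sorted(communities, key=lambda m: -len(m))):
        labels[list(members)] = c
    sizes = pd.Series(labels).value_counts()
    singles = sizes[sizes == 1].index
    if len(singles):
        warnings.warn(
            f"{len(singles)} singleton communities merged into nearest cluster",
            stacklevel=2,
        )
        keep = [c for c in sizes.index if c not in set(singles)]
        centroids = {c: pcs[labels == c].mean(axis=0) for c in keep}
        for c in singles:
            i = int(np.flatnonzero(labels == c)[0])
            labels[i] = min(
                centroids, key=lambda k: np.linalg.norm(pcs[i] - centroids[k])
            )
        labels = pd.factorize(labels)[0]
    return pd.Series(labels, index=normalized.columns, name="cluster")


def find_markers(
    normalized: pd.DataFrame,
    labels: pd.Series,
    criteria: MarkerCriteria | None = None,
) -> dict[int, pd.DataFrame]:
    """One-vs-rest Wilcoxon marker genes per cluster.

    For each cluster, every gene is tested against all remaining cells;
    genes pass when ln((mean_in + 1) / (mean_rest + 1)) > min_lfc, the
    in-cluster detection rate exceeds min_pct, and the BH-adjusted p is
    below max_adj_p. Tables are ranked by fold change, descending.
    Clusters smaller than 3 cells are skipped with a warning.
    """
    crit = criteria or MarkerCriteria()
    labels = labels.loc[normalized.columns]
    if labels.nunique() < 2:
        raise InputError("need >= 2 clusters for marker detection")
    out: dict = {}
    x = normalized.to_numpy(dtype=float)
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {cluster} has < 3 cells; skipped", stacklevel=2)
            continue
        a, b = x[:, mask], x[:, ~mask]
        stat, p = scipy.stats.ranksums(a, b, axis=1)
        tied = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (
            a.mean(axis=1) == b.mean(axis=1)
        )
        p = np.where(tied, 1.0, p)
        mean_in, mean_rest = a.mean(axis=1), b.mean(axis=1)
        lfc = np.log(mean_in + 1.0) - np.log(mean_rest + 1.0)
        pct_in = (a > 0).mean(axis=1)
        table = pd.DataFrame(
            {
                "gene_id": normalized.index,
                "lfc": lfc,
                "pct_in": pct_in,
                "mean_in": mean_in,
                "mean_rest": mean_rest,
                "stat": stat,
                "pvalue": p,
                "padj": bh_adjust(p),
            }
        )
        passed = table[
            (table.lfc > crit.min_lfc)
            & (table.pct_in > crit.min_pct)
            & (table.padj < crit.max_adj_p)
        ]
        out[cluster] = passed.sort_values(
            "lfc", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return out


def top_markers(markers: dict[int, pd.DataFrame], n: int = 10) -> pd.DataFrame:
    """Long-format top-n markers per cluster (the heatmap row layout)."""
    frames = [
        df.head(n).assign(cluster=c)[["cluster", "gene_id", "lfc", "padj"]]
        for c, df in sorted(markers.items())
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def proportion_by_condition(
    labels: pd.Series, condition: pd.Series
) -> pd.DataFrame:
    """Cluster x condition counts, within-cluster proportions, and a
    per-cluster chi-square enrichment test (BH-adjusted).

    Each cluster's condition split is compared against the split over
    all remaining cells (2x2 chi-square with continuity correction off
    for small-sample fidelity to the oracle).
    """
    if condition.empty:
        raise InputError("condition labels are empty")
    condition = condition.loc[labels.index]
    table = pd.crosstab(labels, condition)
    props = table.div(table.sum(axis=1), axis=0)
    pvals = []
    for c in table.index:
        inside = table.loc[c].to_numpy()
        outside = table.drop(index=c).sum(axis=0).to_numpy()
        cont = np.vstack([inside, outside])
        if cont.sum(axis=0).min() == 0 or cont.sum(axis=1).min() == 0:
            pvals.append(1.0)
        else:
            _, p, _, _ = scipy.stats.chi2_contingency(cont, correction=False)
            pvals.append(p)
    out = table.add_prefix("n_").join(props.add_prefix("prop_"))
    out["pvalue"] = pvals
    out["padj"] = bh_adjust(pvals)
    return out


def select_variable_features(
    normalized: pd.DataFrame, n_features: int = 2000
) -> list[str]:
    """Rank genes by standardized dispersion (variance / mean within
    mean bins) and keep the top n."""
    mean = normalized.mean(axis=1)
    var = normalized.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var / mean).replace([np.inf, -np.inf], np.nan).fillna(0.0)
    bins = pd.qcut(mean.rank(method="first"), q=min(20, len(mean)), duplicates="drop")
    z = disp.groupby(bins, observed=True).transform(
        lambda d: (d - d.mean()) / (d.std() if d.std() > 0 else 1.0)
    )
    return z.sort_values(ascending=False).head(n_features).index.tolist()


def transfer_scores(
    reference: pd.DataFrame,
    ref_labels: pd.Series,
    query: pd.DataFrame,
    n_features: int = 2000,
) -> pd.DataFrame:
    """Spot x cluster prediction scores via NNLS projection on centroids.

    The top shared variable features are selected from the reference;
    per-cluster centroids are computed; each query spot's profile is fit
    by non-negative least squares on the centroid matrix and the
    coefficients are normalized to sum to one. All-zero spots get
    uniform scores with a warning.
    """
    shared = reference.index.intersection(query.index)
    if len(shared) == 0:
        raise InputError("no genes shared between reference and query")
    features = [
        g for g in select_variable_features(reference.loc[shared], n_features)
    ]
    ref = reference.loc[features]
    ref_labels = ref_labels.loc[reference.columns]
    clusters = sorted(ref_labels.unique())
    centroids = np.column_stack(
        [ref.loc[:, (ref_labels == c).to_numpy()].mean(axis=1) for c in clusters]
    )
    q = query.loc[features].to_numpy(dtype=float)
    scores = np.zeros((q.shape[1], len(clusters)))
    n_zero = 0
    for j in range(q.shape[1]):
        col = q[:, j]
        if not col.any():
            scores[j] = 1.0 / len(clusters)
            n_zero += 1
            continue
        coef, _ = nnls(centroids, col)
        total = coef.sum()
        scores[j] = coef / total if total > 0 else 1.0 / len(clusters)
    if n_zero:
        warnings.warn(f"{n_zero} all-zero query spots got uniform scores", stacklevel=2)
    return pd.DataFrame(scores, index=query.columns, columns=[str(c) for c in clusters])


def overlay_scores(
    scores: pd.DataFrame, lattice, min_score: float = 0.5
) -> pd.DataFrame:
    """Per-spot winning cluster with coordinates; flags low-confidence spots.

    Spots whose best score falls below ``min_score`` are reported as
    unconfident — the situation where a reference cluster fails to
    overlap any spatial region.
    """
    lattice_ids = lattice.spot_ids if hasattr(lattice, "spot_ids") else list(lattice)
    if set(scores.index) != set(lattice_ids):
        raise InputError("score spot ids do not match the lattice")
    best = scores.idxmax(axis=1)
    best_score = scores.max(axis=1)
    out = scores.copy()
    out["winning_cluster"] = best
    out["max_score"] = best_score
    out["confident"] = best_score >= min_score
    coords = getattr(lattice, "coords", None)
    if coords is not None:
        out = out.join(coords.set_index("spot_id")[["x_um", "y_um"]])
    return out
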