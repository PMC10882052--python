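"""Hex adjacency, Moran's I vs brute force, NMF recovery, border analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from zonescope import spatial, syndata
from zonescope.errors import ConfigurationError, InputError

from conftest import moran_bruteforce


class TestAdjacency:
    def test_two_spots_one_edge(self):
        coords = pd.DataFrame(
            {"spot_id": ["a", "b"], "array_row": [0, 0], "array_col": [0, 1],
             "x_um": [0.0, 100.0], "y_um": [0.0, 0.0]}
        )
        lat = spatial.build_adjacency(coords)
        assert lat.adjacency.sum() == 2  # one symmetric edge

    def test_hex_neighbor_counts(self, hex_lattice_small):
        deg = np.asarray(hex_lattice_small.adjacency.sum(axis=1)).ravel()
        coords = hex_lattice_small.coords
        interior = (
            coords.array_row.between(1, 4) & coords.array_col.between(1, 4)
        ).to_numpy()
        assert (deg[interior] == 6).all()
        corner = ((coords.array_row == 0) & (coords.array_col == 0)).to_numpy()
        assert deg[corner][0] in (2, 3)
        assert (deg <= 6).all()

    def test_symmetric_irreflexive(self, hex_lattice_small):
        a = hex_lattice_small.adjacency.toarray()
        assert (a == a.T).all() and (np.diag(a) == 0).all()

    def test_duplicate_coordinates_rejected(self):
        coords = pd.DataFrame(
            {"spot_id": ["a", "b"], "array_row": [0, 0], "array_col": [0, 0],
             "x_um": [0.0, 0.0], "y_um": [0.0, 0.0]}
        )
        with pytest.raises(InputError):
            spatial.build_adjacency(coords)


class TestMoran:
    def test_matches_bruteforce_on_hex(self, hex_lattice_small):
        rng = np.random.default_rng(3)
        for _ in range(5):
            vals = rng.normal(size=36)
            assert spatial.global_moran(vals, hex_lattice_small) == pytest.approx(
                moran_bruteforce(vals, hex_lattice_small.adjacency), abs=1e-10
            )

    def test_alternating_four_cycle_is_minus_one(self):
        coords = pd.DataFrame(
            {"spot_id": list("abcd"), "array_row": [0, 0, 1, 1],
             "array_col": [0, 1, 1, 0],
             "x_um": [0.0, 1.0, 1.0, 0.0], "y_um": [0.0, 0.0, 1.0, 1.0]}
        )
        lat = spatial.build_adjacency(coords)
        assert spatial.global_moran(np.array([1.0, -1.0, 1.0, -1.0]), lat) == -1.0

    def test_constant_input_warns_and_returns_zero(self, hex_lattice_small):
        with pytest.warns(UserWarning, match="constant"):
            assert spatial.global_moran(np.ones(36), hex_lattice_small) == 0.0
        with pytest.warns(UserWarning):
            assert (spatial.local_autocorrelation(np.ones(36), hex_lattice_small) == 0).all()

    def test_contiguous_blocks_on_path_positive(self):
        coords = pd.DataFrame(
            {"spot_id": [f"s{i}" for i in range(8)], "array_row": 0,
             "array_col": range(8), "x_um": np.arange(8.0), "y_um": 0.0}
        )
        lat = spatial.build_adjacency(coords)
        vals = np.array([0.0] * 4 + [5.0] * 4)
        i = spatial.global_moran(vals, lat)
        assert i > 0
        assert i == pytest.approx(moran_bruteforce(vals, lat.adjacency), abs=1e-10)

    def test_local_sums_to_s0_times_global(self, hex_lattice_small):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=36)
        local = spatial.local_autocorrelation(vals, hex_lattice_small)
        s0 = hex_lattice_small.adjacency.sum()
        assert local.sum() == pytest.approx(
            s0 * spatial.global_moran(vals, hex_lattice_small), rel=1e-10
        )

    def test_bounded_for_many_fields(self, hex_lattice_small):
        rng = np.random.default_rng(5)
        for _ in range(10):
            i = spatial.global_moran(rng.normal(size=36), hex_lattice_small)
            assert -1.5 <= i <= 1.5  # binary-weight Moran can slightly exceed [-1,1]


class TestNmf:
    def test_rank_one_matrix_exactly_recovered(self):
        rng = np.random.default_rng(0)
        x = np.outer(rng.uniform(1, 2, 30), rng.uniform(1, 2, 15))
        model = spatial.nmf(pd.DataFrame(x), k=1, max_iter=2000, tol=1e-12, seed=0)
        rel = np.linalg.norm(x - (model.w @ model.h).T) / np.linalg.norm(x)
        assert rel < 1e-3

    def test_loss_trace_non_increasing(self, visium):
        counts, _, _ = visium
        model = spatial.nmf(counts, k=3, seed=1)
        diffs = np.diff(model.loss_trace)
        assert (diffs <= 1e-9 * np.abs(model.loss_trace[:-1])).all()

    def test_planted_factors_recovered(self, visium):
        counts, _, truth = visium
        model = spatial.nmf(counts, k=3, seed=1)
        corr = np.array(
            [
                [np.corrcoef(truth.planted_w[:, i], model.w[:, j])[0, 1] for j in range(3)]
                for i in range(3)
            ]
        )
        rows, cols = linear_sum_assignment(-corr)
        assert (corr[rows, cols] >= 0.9).all()

    def test_seeded_runs_identical(self, visium):
        counts, _, _ = visium
        a = spatial.nmf(counts, k=3, seed=2)
        b = spatial.nmf(counts, k=3, seed=2)
        assert np.array_equal(a.w, b.w) and np.array_equal(a.h, b.h)

    def test_reconstruction_competitive_with_sklearn(self, visium):
        from sklearn.decomposition import NMF as SkNMF

        counts, _, _ = visium
        x = counts.to_numpy(dtype=float).T
        ours = spatial.nmf(counts, k=3, max_iter=400, seed=0)
        sk = SkNMF(n_components=3, init="random", random_state=0, max_iter=400)
        w = sk.fit_transform(x)
        err_ours = np.linalg.norm(x - ours.w @ ours.h)
        err_sk = np.linalg.norm(x - w @ sk.components_)
        assert err_ours <= 1.1 * err_sk

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            spatial.nmf(pd.DataFrame([[1.0, -1.0], [0.0, 2.0], [1.0, 1.0]]), k=1)

    def test_k_too_large_rejected(self, visium):
        counts, _, _ = visium
        with pytest.raises(ConfigurationError):
            spatial.nmf(counts.iloc[:5, :4], k=5)


class TestFactorLocalization:
    def test_confined_factor_selected(self, visium):
        counts, _, truth = visium
        model = spatial.nmf(counts, k=3, seed=1)
        picked = spatial.pick_injury_factor(model, set(truth.injury_spots))
        scores = spatial.localize_factor(model, set(truth.injury_spots))
        matched = np.argmax(
            [np.corrcoef(truth.planted_w[:, truth.injury_factor], model.w[:, j])[0, 1]
             for j in range(3)]
        )
        assert picked == matched
        assert scores[picked] > 2 * np.delete(scores, picked).max()

    def test_uniform_factor_scores_near_one(self):
        model = spatial.FactorModel(
            w=np.ones((10, 1)), h=np.ones((1, 4)), loss_trace=[1.0],
            spot_ids=[f"s{i}" for i in range(10)], gene_ids=list("abcd"),
        )
        score = spatial.localize_factor(model, {"s0", "s1", "s2"})
        assert score[0] == pytest.approx(1.0, rel=1e-6)

    def test_top_genes_ranked_and_sized(self, visium):
        counts, _, truth = visium
        model = spatial.nmf(counts, k=3, seed=1)
        injury = spatial.pick_injury_factor(model, set(truth.injury_spots))
        top = spatial.top_factor_genes(model, injury, n=10)
        assert len(top) == 10
        planted = set(truth.marker_genes[truth.injury_factor])
        assert len(set(top) & planted) >= 8
        top1 = spatial.top_factor_genes(model, injury, n=1)
        weights = dict(zip(model.gene_ids, model.h[injury]))
        assert weights[top1[0]] == max(weights.values())


class TestClustersAndBorders:
    def test_region_neighbors_ring_around_center(self):
        coords = syndata.hex_lattice(3, 3)
        lat = spatial.build_adjacency(coords)
        center = coords.spot_id[ (coords.array_row == 1) & (coords.array_col == 1) ].iloc[0]
        labels = np.where(coords.spot_id == center, 1, 0)
        border = spatial.region_neighbors(labels, 1, lat)
        # center of a 3x3 offset hex grid touches its full hex neighborhood
        deg = lat.adjacency[coords.index[coords.spot_id == center][0]].sum()
        assert len(border) == deg == 6
        assert center not in border

    def test_border_disjoint_and_adjacent(self, visium):
        counts, coords, truth = visium
        lat = spatial.build_adjacency(coords)
        model = spatial.nmf(counts, k=3, seed=1)
        labels = spatial.cluster_spots(model, 3, seed=0)
        border = spatial.region_neighbors(labels, labels[0], lat)
        target = set(np.array(lat.spot_ids)[labels == labels[0]])
        assert border.isdisjoint(target)
        for b in border:
            assert any(n in target for n in lat.neighbors(b))

    def test_whole_lattice_cluster_has_empty_border(self, hex_lattice_small):
        labels = np.zeros(36, dtype=int)
        assert spatial.region_neighbors(labels, 0, hex_lattice_small) == set()

    def test_cluster_spots_deterministic(self, visium):
        counts, _, _ = visium
        model = spatial.nmf(counts, k=3, seed=1)
        a = spatial.cluster_spots(model, 3, seed=5)
        b = spatial.cluster_spots(model, 3, seed=5)
        assert np.array_equal(a, b)


class TestInjuryBorderDe:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 4))
        normalized = pd.DataFrame(
            np.hstack([base, base]), index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(8)],
        )
        de = spatial.de_injury_vs_border(
            normalized, {f"s{i}" for i in range(4)}, {f"s{i}" for i in range(4, 8)}
        )
        assert (de.padj > 0.9).all()

    def test_exclusive_gene_tops_ranking(self):
        rng = np.random.default_rng(1)
        normalized = pd.DataFrame(
            rng.normal(0, 0.1, size=(30, 12)), index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(12)],
        ).abs()
        injury = {f"s{i}" for i in range(6)}
        border = {f"s{i}" for i in range(6, 12)}
        normalized.loc["g0", list(injury)] = 5.0
        normalized.loc["g0", list(border)] = 0.0
        de = spatial.de_injury_vs_border(normalized, injury, border)
        assert de.gene_id.iloc[0] == "g0" and de.lfc.iloc[0] > 0

    def test_small_groups_rejected(self):
        normalized = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(InputError):
            spatial.de_injury_vs_border(normalized, {"a", "b"}, {"c", "d"})
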