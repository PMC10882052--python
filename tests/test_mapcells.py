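"""Cell clustering, marker criteria, proportions, and transfer scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from zonescope import mapcells, qc, syndata
from zonescope.errors import InputError


@pytest.fixture(scope="module")
def sc_data():
    counts, truth = syndata.simulate_sc_counts(120, seed=7)
    normalized = qc.lognormalize(counts)
    return counts, normalized, truth


def ranksum_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Independent rank-sum p: explicit rank statistic + normal approximation."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    w = ranks[: len(a)].sum()
    n1, n2 = len(a), len(b)
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - mu) / sigma
    return 2 * scipy.stats.norm.sf(abs(z))


class TestClusterCells:
    def test_separated_programs_recovered_exactly(self, sc_data):
        _, normalized, truth = sc_data
        labels = mapcells.cluster_cells(normalized, n_pcs=5, seed=0)
        assert adjusted_rand_score(truth.cluster.loc[labels.index], labels) == 1.0

    def test_deterministic(self, sc_data):
        _, normalized, _ = sc_data
        a = mapcells.cluster_cells(normalized, n_pcs=5, seed=0)
        b = mapcells.cluster_cells(normalized, n_pcs=5, seed=0)
        assert a.equals(b)

    def test_too_few_cells_rejected(self):
        tiny = pd.DataFrame(np.ones((10, 5)), columns=[f"c{i}" for i in range(5)])
        with pytest.raises(InputError):
            mapcells.cluster_cells(tiny, n_pcs=2, n_neighbors=10)


class TestFindMarkers:
    def test_exclusive_gene_is_marker(self):
        rng = np.random.default_rng(0)
        normalized = pd.DataFrame(
            rng.uniform(0.5, 1.0, size=(10, 40)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"c{i}" for i in range(40)],
        )
        labels = pd.Series([0] * 20 + [1] * 20, index=normalized.columns)
        normalized.iloc[0, :20] = 5.0
        normalized.iloc[0, 20:] = 0.0
        markers = mapcells.find_markers(normalized, labels)
        assert "g0" in markers[0].gene_id.tolist()
        assert "g0" not in markers[1].gene_id.tolist()

    def test_low_detection_rate_excluded(self):
        rng = np.random.default_rng(1)
        normalized = pd.DataFrame(
            rng.uniform(0.5, 1.0, size=(10, 40)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"c{i}" for i in range(40)],
        )
        labels = pd.Series([0] * 20 + [1] * 20, index=normalized.columns)
        # strong but detected in only 20% of in-cluster cells
        normalized.iloc[0, :] = 0.0
        normalized.iloc[0, :4] = 50.0
        markers = mapcells.find_markers(normalized, labels)
        assert "g0" not in markers[0].gene_id.tolist()

    def test_pvalues_match_ranksum_oracle(self):
        rng = np.random.default_rng(2)
        normalized = pd.DataFrame(
            rng.normal(1, 0.3, size=(8, 30)).clip(0),
            index=[f"g{i}" for i in range(8)],
            columns=[f"c{i}" for i in range(30)],
        )
        labels = pd.Series([0] * 12 + [1] * 18, index=normalized.columns)
        normalized.iloc[:, :12] += 0.7  # lift cluster 0 so every gene ranks as its marker
        markers = mapcells.find_markers(
            normalized, labels,
            mapcells.MarkerCriteria(min_lfc=1e-9, min_pct=1e-9, max_adj_p=2.0),
        )
        table = markers[0].set_index("gene_id")
        for gene in normalized.index:
            a = normalized.loc[gene].iloc[:12].to_numpy()
            b = normalized.loc[gene].iloc[12:].to_numpy()
            assert table.loc[gene, "pvalue"] == pytest.approx(
                ranksum_oracle(a, b), rel=1e-9
            )

    def test_planted_markers_recovered_without_false_positives(self, sc_data):
        _, normalized, truth = sc_data
        labels = mapcells.cluster_cells(normalized, n_pcs=5, seed=0)
        markers = mapcells.find_markers(normalized, labels)
        # map detected clusters onto truth clusters by majority
        for c, table in markers.items():
            cells = labels[labels == c].index
            true_c = truth.cluster.loc[cells].mode()[0]
            planted = set(truth.marker_genes[true_c])
            found = set(table.gene_id)
            assert planted <= found
            assert not found - planted  # nothing but planted markers

    def test_tiny_cluster_skipped_with_warning(self, sc_data):
        _, normalized, _ = sc_data
        labels = pd.Series(0, index=normalized.columns)
        labels.iloc[:2] = 1
        with pytest.warns(UserWarning, match="< 3 cells"):
            markers = mapcells.find_markers(normalized, labels)
        assert 1 not in markers


class TestProportions:
    def test_counts_conserve_cells(self, sc_data):
        _, normalized, truth = sc_data
        labels = mapcells.cluster_cells(normalized, n_pcs=5, seed=0)
        table = mapcells.proportion_by_condition(labels, truth.condition)
        n_cols = [c for c in table.columns if c.startswith("n_")]
        assert table[n_cols].to_numpy().sum() == len(labels)

    def test_skewed_cluster_flagged(self):
        rng = np.random.default_rng(3)
        labels = pd.Series([0] * 100 + [1] * 100, index=[f"c{i}" for i in range(200)])
        cond = pd.Series(
            ["injured" if (i < 100 and rng.random() < 0.9) or (i >= 100 and rng.random() < 0.5) else "uninjured"
             for i in range(200)],
            index=labels.index,
        )
        table = mapcells.proportion_by_condition(labels, cond)
        assert table.loc[0, "padj"] < 0.05
        chi2_p = scipy.stats.chi2_contingency(
            pd.crosstab(labels, cond).to_numpy(), correction=False
        )[1]
        assert table.loc[0, "pvalue"] == pytest.approx(chi2_p, rel=1e-9)

    def test_balanced_proportions_near_half(self, sc_data):
        _, normalized, truth = sc_data
        labels = mapcells.cluster_cells(normalized, n_pcs=5, seed=0)
        table = mapcells.proportion_by_condition(labels, truth.condition)
        balanced = [
            c for c, t in labels.groupby(labels).groups.items()
            if truth.cluster.loc[t].mode()[0] != "c1"  # c1 is the enriched cluster
        ]
        for c in balanced:
            assert abs(table.loc[c, "prop_injured"] - 0.5) < 0.2


class TestTransferScores:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(4)
        ref = pd.DataFrame(
            rng.uniform(0, 3, size=(50, 30)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"c{i}" for i in range(30)],
        )
        labels = pd.Series([0] * 10 + [1] * 10 + [2] * 10, index=ref.columns)
        for c in (0, 1, 2):
            ref.iloc[c * 15 : (c + 1) * 15, (labels == c).to_numpy()] += 6.0
        return ref, labels

    def test_centroid_query_scores_high(self, reference):
        ref, labels = reference
        centroid = ref.loc[:, (labels == 1).to_numpy()].mean(axis=1)
        scores = mapcells.transfer_scores(ref, labels, centroid.to_frame("q"))
        assert scores.loc["q", "1"] >= 0.99

    def test_equal_mixture_splits_scores(self, reference):
        ref, labels = reference
        c0 = ref.loc[:, (labels == 0).to_numpy()].mean(axis=1)
        c2 = ref.loc[:, (labels == 2).to_numpy()].mean(axis=1)
        scores = mapcells.transfer_scores(ref, labels, (0.5 * c0 + 0.5 * c2).to_frame("mix"))
        assert 0.4 <= scores.loc["mix", "0"] <= 0.6
        assert 0.4 <= scores.loc["mix", "2"] <= 0.6

    def test_rows_sum_to_one(self, reference, sc_data):
        ref, labels = reference
        rng = np.random.default_rng(5)
        query = pd.DataFrame(
            rng.uniform(0, 3, size=(50, 20)), index=ref.index,
            columns=[f"s{i}" for i in range(20)],
        )
        scores = mapcells.transfer_scores(ref, labels, query)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-8)
        assert (scores.to_numpy() >= 0).all()

    def test_gene_order_permutation_invariant(self, reference):
        ref, labels = reference
        rng = np.random.default_rng(6)
        query = pd.DataFrame(
            rng.uniform(0, 3, size=(50, 5)), index=ref.index,
            columns=[f"s{i}" for i in range(5)],
        )
        a = mapcells.transfer_scores(ref, labels, query)
        perm = rng.permutation(ref.index)
        b = mapcells.transfer_scores(ref.loc[perm], labels, query.loc[perm])
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-8)

    def test_zero_spot_gets_uniform_scores(self, reference):
        ref, labels = reference
        query = pd.DataFrame(0.0, index=ref.index, columns=["empty"])
        with pytest.warns(UserWarning, match="all-zero"):
            scores = mapcells.transfer_scores(ref, labels, query)
        assert np.allclose(scores.loc["empty"], 1 / 3)

    def test_disjoint_gene_sets_rejected(self, reference):
        ref, labels = reference
        query = pd.DataFrame(1.0, index=["x1", "x2"], columns=["s"])
        with pytest.raises(InputError):
            mapcells.transfer_scores(ref, labels, query)


class TestOverlay:
    def test_winner_and_confidence(self):
        coords = syndata.hex_lattice(2, 2)
        from zonescope import spatial

        lat = spatial.build_adjacency(coords)
        scores = pd.DataFrame(
            {"0": [0.9, 0.4, 0.2, 1 / 3], "1": [0.05, 0.35, 0.5, 1 / 3],
             "2": [0.05, 0.25, 0.3, 1 / 3]},
            index=lat.spot_ids,
        )
        out = mapcells.overlay_scores(scores, lat)
        assert out.winning_cluster.iloc[0] == "0"
        assert bool(out.confident.iloc[0]) is True
        assert bool(out.confident.iloc[1]) is False

    def test_id_mismatch_rejected(self, hex_lattice_small):
        scores = pd.DataFrame({"0": [1.0]}, index=["nope"])
        with pytest.raises(InputError):
            mapcells.overlay_scores(scores, hex_lattice_small)
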