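"""Feature engine: catalogue structure, hand-checked values, equivariance."""

import numpy as np
import pandas as pd
import pytest

import oracles as orc
from connectoml.connectome import binarize
from connectoml.datamodel import BinaryGraph, Cohort, ConnectivityMatrix, ConnectomlError, Subject
from connectoml.features import (
    CATEGORY_SIZES,
    catalogue,
    compute_global,
    compute_local,
    feature_table,
    group_contrast,
    local_column_names,
    local_measure_names,
    measure_names,
)


def graph_pair(A):
    """Binary graph + matching weighted matrix (weights = 0.5 * A)."""
    A = np.asarray(A)
    gb = BinaryGraph("s", A.astype(int), tau=0.2)
    gw = ConnectivityMatrix("s", 0.5 * A, stage="rectified")
    return gb, gw


K3 = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
P3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
S4 = np.zeros((4, 4), int)
S4[0, 1:] = S4[1:, 0] = 1


class TestCatalogue:
    def test_category_sizes_and_total(self):
        cat = catalogue()
        assert len(cat) == 69
        for category, size in CATEGORY_SIZES.items():
            assert len(measure_names(category)) == size

    def test_paper_named_measures_present_in_category(self):
        gb = measure_names("global_binary")
        for name in ("degree_assortativity", "maximal_clique_count",
                     "transitivity", "average_shortest_path_length",
                     "number_of_edges", "global_clustering", "stoer_wagner_cut"):
            assert name in gb
        gw = measure_names("global_weighted")
        for name in ("dijkstra_path_length", "weighted_wiener_index",
                     "conductance"):
            assert name in gw
        lb = measure_names("local_binary")
        for name in ("degree_centrality", "betweenness_centrality",
                     "closeness_centrality", "load_centrality",
                     "pagerank_centrality", "greedy_color_index",
                     "local_reaching_centrality", "node_maximal_clique_count"):
            assert name in lb
        lw = measure_names("local_weighted")
        for name in ("closeness_vitality", "effective_size", "weighted_degree"):
            assert name in lw

    def test_local_measures_number_26(self):
        assert len(local_measure_names()) == 26


class TestGlobalValues:
    def test_triangle(self):
        v = compute_global(*graph_pair(K3))
        assert v["transitivity"] == 1.0
        assert v["number_of_edges"] == 3
        assert v["average_shortest_path_length"] == 1.0
        assert v["maximal_clique_count"] == 1

    def test_path_p3(self):
        v = compute_global(*graph_pair(P3))
        assert v["wiener_index"] == 4.0  # brute force: 1 + 1 + 2
        assert v["average_shortest_path_length"] == pytest.approx(4 / 3)

    def test_star_assortativity(self):
        v = compute_global(*graph_pair(S4))
        assert v["degree_assortativity"] == pytest.approx(-1.0)
        assert v["degree_assortativity"] == pytest.approx(orc.assortativity(S4))

    def test_disconnected_flags_nan_only_for_path_measures(self):
        A = np.zeros((4, 4), int)
        A[0, 1] = A[1, 0] = 1
        v = compute_global(*graph_pair(A))
        assert np.isnan(v["average_shortest_path_length"])
        assert np.isnan(v["diameter"])
        assert v["number_of_edges"] == 1
        assert v["density"] == pytest.approx(1 / 6)


class TestLocalValues:
    def test_k3_degree_centrality_normalized(self):
        df = compute_local(*graph_pair(K3))
        assert np.allclose(df["degree_centrality"], 1.0)

    def test_p3_middle_betweenness(self):
        df = compute_local(*graph_pair(P3))
        assert df["betweenness_centrality"][1] == pytest.approx(1.0)
        np.testing.assert_allclose(df["betweenness_centrality"],
                                   orc.betweenness(P3), atol=1e-12)

    def test_weighted_degree_is_row_sum(self, rng):
        from conftest import random_rectified

        m = random_rectified(8, rng)
        gb = binarize(m, 0.2)
        df = compute_local(gb, m)
        np.testing.assert_allclose(df["weighted_degree"], m.W.sum(axis=0))

    def test_shape_and_column_order(self):
        df = compute_local(*graph_pair(K3))
        assert df.shape == (3, 26)
        assert list(df.columns) == local_measure_names()


class TestFeatureTable:
    def test_local_block_flattens_to_n_times_26(self, tiny_cohort):
        t = feature_table(tiny_cohort, 0.2, scope="both")
        assert t.local_df.shape == (9, 12 * 26)
        assert t.global_df.shape == (9, 43)
        assert t.local_df.columns[0] == "roi000__degree_centrality"

    def test_identical_subjects_identical_rows(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.4
        W[2, 3] = W[3, 2] = 0.6
        W[3, 4] = W[4, 3] = 0.3
        subs = [Subject(ConnectivityMatrix(f"s{i}", W), label=i % 2)
                for i in range(2)]
        t = feature_table(Cohort(subs), 0.2, scope="both")
        np.testing.assert_array_equal(t.global_df.iloc[0], t.global_df.iloc[1])
        np.testing.assert_array_equal(t.local_df.iloc[0], t.local_df.iloc[1])

    def test_roi_permutation_equivariance(self, rng):
        from conftest import random_rectified

        m = random_rectified(9, rng, density=0.7)
        perm = rng.permutation(9)
        mp = ConnectivityMatrix("p", m.W[np.ix_(perm, perm)], stage="rectified")
        g1 = compute_global(binarize(m, 0.2), m)
        g2 = compute_global(binarize(mp, 0.2), mp)
        pd.testing.assert_series_equal(g1, g2, atol=1e-9, rtol=1e-9)
        l1 = compute_local(binarize(m, 0.2), m)
        l2 = compute_local(binarize(mp, 0.2), mp)
        np.testing.assert_allclose(l2.to_numpy(), l1.to_numpy()[perm],
                                   atol=1e-8)


class TestGroupContrast:
    def test_equal_groups_ratio_one(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0, 2.0]})
        r = group_contrast(df, np.array([0, 1, 0, 1]))
        assert r.loc["a", "ratio"] == pytest.approx(1.0)

    def test_planted_doubling(self, rng):
        base = rng.uniform(1, 2, 50)
        df = pd.DataFrame({"a": np.concatenate([base, 2 * base])})
        y = np.array([0] * 50 + [1] * 50)
        assert group_contrast(df, y).loc["a", "ratio"] == pytest.approx(2.0)

    def test_zero_denominator_flagged_nan(self):
        df = pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0]})
        r = group_contrast(df, np.array([0, 0, 1, 1]))
        assert np.isnan(r.loc["a", "ratio"])

    def test_single_class_rejected(self):
        with pytest.raises(ConnectomlError):
            group_contrast(pd.DataFrame({"a": [1.0]}), np.array([1]))

    def test_clustering_direction_on_strong_cohort(self, strong_tables):
        r = group_contrast(strong_tables.global_df, strong_tables.labels)
        assert r.loc["global_clustering", "ratio"] < 1


def test_local_column_names_cover_all_rois():
    names = local_column_names(164)
    assert len(names) == 4264
    assert names[-1] == "roi163__closeness_vitality"
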