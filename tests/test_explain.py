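"""Attribution axioms, percentage normalization, GNN mask behaviour."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from connectoml.datamodel import ConnectomlError
from connectoml.explain import (
    feature_attribution,
    gnn_explain,
    importance_percentages,
    rank_explained_features,
)
from connectoml.gnn import GcnModel, GnnConfig, GraphSample, normalize_adjacency


@pytest.fixture(scope="module")
def fitted_stump():
    """Depth-1 tree splitting only on feature 1 of 3."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 3))
    y = (X[:, 1] > 0).astype(int)
    clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    return clf, X, y


class TestTreeAttribution:
    def test_null_player_gets_zero(self, fitted_stump):
        clf, X, _ = fitted_stump
        attr = feature_attribution(clf, X[:20], mode="exact")
        assert np.allclose(attr.phi[:, 0], 0.0)
        assert np.allclose(attr.phi[:, 2], 0.0)

    def test_stump_concentrates_mass_on_split_feature(self, fitted_stump):
        clf, X, _ = fitted_stump
        attr = feature_attribution(clf, X[:20], mode="exact")
        assert attr.mean_abs[1] > 0
        assert attr.mean_abs[[0, 2]].max() == 0.0

    def test_stump_attribution_matches_hand_enumeration(self, fitted_stump):
        """Depth-1 Shapley closed form: phi = f(x) - E[f]."""
        clf, X, _ = fitted_stump
        attr = feature_attribution(clf, X[:10], mode="exact")
        preds = clf.predict_proba(X[:10])[:, 1]
        np.testing.assert_allclose(attr.phi[:, 1], preds - attr.base_value,
                                   atol=1e-12)

    def test_additivity_for_forest(self, rng):
        X = rng.standard_normal((60, 4))
        y = ((X[:, 0] + X[:, 2]) > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=10, max_depth=3,
                                    random_state=0).fit(X, y)
        attr = feature_attribution(rf, X[:10], mode="exact")
        preds = rf.predict_proba(X[:10])[:, 1]
        np.testing.assert_allclose(attr.base_value + attr.phi.sum(axis=1),
                                   preds, atol=1e-10)

    def test_duplicated_features_share_attribution(self, rng):
        """Symmetry axiom on a pair of identical columns."""
        X = rng.standard_normal((300, 2))
        X[:, 1] = X[:, 0]
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=40, max_depth=2,
                                    random_state=0).fit(X, y)
        attr = feature_attribution(rf, X[:40], mode="exact")
        a, b = attr.mean_abs
        assert a + b > 0
        assert abs(a - b) / (a + b) < 0.25  # forest splits shared across copies

    def test_sampling_mode_approximates_exact(self, rng):
        """Interventional sampling vs path-dependent exact mode: the two
        conditioning conventions agree loosely on a shallow tree, and
        exactly on features the tree never uses."""
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        clf = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
        exact = feature_attribution(clf, X[:5], mode="exact")
        approx = feature_attribution(clf, X[:5], mode="sampling",
                                     n_permutations=400, seed=0)
        np.testing.assert_allclose(approx.phi, exact.phi, atol=0.25)
        assert np.allclose(approx.phi[:, 1:], 0.0, atol=0.05)
        assert np.all(np.sign(approx.phi[:, 0]) == np.sign(exact.phi[:, 0]))

    def test_depth_limit_enforced(self, rng):
        X = rng.standard_normal((400, 3))
        y = (rng.random(400) > 0.5).astype(int)
        deep = DecisionTreeClassifier(random_state=0).fit(X, y)
        if deep.tree_.max_depth > 10:
            with pytest.raises(ConnectomlError, match="depth"):
                feature_attribution(deep, X[:2], mode="exact")


class TestPercentages:
    def test_normalization(self):
        pct = importance_percentages({"a": 2.0, "b": 8.0})
        assert pct["a"] == pytest.approx(20.0)
        assert pct["b"] == pytest.approx(80.0)
        assert pct.sum() == pytest.approx(100.0)

    def test_single_feature_is_hundred(self):
        assert importance_percentages({"x": 3.0})["x"] == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ConnectomlError):
            importance_percentages({"a": 0.0, "b": 0.0})

    def test_negative_rejected(self):
        with pytest.raises(ConnectomlError):
            importance_percentages({"a": -1.0, "b": 2.0})

    def test_planted_single_informative_feature_dominates(self, rng):
        X = rng.standard_normal((200, 5))
        y = (X[:, 3] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=30, max_depth=3,
                                    random_state=0).fit(X, y)
        attr = feature_attribution(rf, X, mode="exact")
        pct = importance_percentages(pd.Series(attr.mean_abs))
        assert pct.iloc[3] >= 50.0


class TestRanking:
    def test_concentrated_mask_ranks_first(self):
        df = rank_explained_features({"a": 0.1, "b": 0.9, "c": 0.2})
        assert df.iloc[0]["measure"] == "b"

    def test_uniform_ties_lexicographic(self):
        df = rank_explained_features({"b": 0.5, "a": 0.5, "c": 0.5})
        assert list(df["measure"]) == ["a", "b", "c"]

    def test_csv_roundtrip(self, tmp_path):
        df = rank_explained_features({"a": 0.3, "b": 0.7})
        df.to_csv(tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv", index_col="rank")
        assert list(back["measure"]) == list(df["measure"])


MOTIF = 5  # label = presence of a clique on nodes 0..MOTIF-1


@pytest.fixture(scope="module")
def trained_gcn():
    """GCN trained to detect a planted clique among the first five nodes."""
    rng = np.random.default_rng(1)
    cfg = GnnConfig(gcn_channels=(16, 16), max_epochs=600, patience=600,
                    learning_rate=0.02, seed=0)
    model = GcnModel(2, cfg)
    samples = []
    for i in range(40):
        n = 10
        A = (rng.random((n, n)) < 0.12).astype(float)
        A = np.triu(A, 1)
        y = i % 2
        if y:
            for a in range(MOTIF):
                for b in range(a + 1, MOTIF):
                    A[a, b] = 1.0
        A = A + A.T
        X = np.column_stack([np.ones(n), A.sum(axis=0) / n])
        samples.append(GraphSample(normalize_adjacency(A), X, y))
    from connectoml.gnn import train

    params, _ = train(model, samples[:32], samples[32:], cfg)
    return model, params, samples


class TestGnnExplain:
    def test_open_masks_reproduce_prediction(self, trained_gcn):
        model, params, samples = trained_gcn
        s = samples[1]
        p0, _ = model.forward(s.A_norm, s.X, params)
        p1, _ = model.forward(s.A_norm * 1.0, s.X * 1.0, params)
        np.testing.assert_array_equal(p0, p1)

    def test_masks_bounded_and_edge_mask_symmetric(self, trained_gcn):
        model, params, samples = trained_gcn
        ex = gnn_explain(model, params, samples[1], steps=30, seed=0)
        assert np.all(ex.edge_mask >= 0) and np.all(ex.edge_mask <= 1)
        assert np.all(ex.feature_mask >= 0) and np.all(ex.feature_mask <= 1)
        np.testing.assert_array_equal(ex.edge_mask, ex.edge_mask.T)

    def test_huge_size_penalty_closes_masks(self, trained_gcn):
        model, params, samples = trained_gcn
        ex = gnn_explain(model, params, samples[1], lambda_size=1e4,
                         lambda_entropy=0.0, steps=120, seed=0)
        assert ex.feature_mask.mean() < 0.2
        off = ex.edge_mask[ex.edge_mask > 0]
        assert off.mean() < 0.2 if off.size else True

    def test_deterministic_given_seed(self, trained_gcn):
        model, params, samples = trained_gcn
        a = gnn_explain(model, params, samples[1], steps=20, seed=3)
        b = gnn_explain(model, params, samples[1], steps=20, seed=3)
        np.testing.assert_array_equal(a.edge_mask, b.edge_mask)
        np.testing.assert_array_equal(a.feature_mask, b.feature_mask)

    def test_model_parameters_frozen(self, trained_gcn):
        model, params, samples = trained_gcn
        before = {k: v.copy() for k, v in params.items()}
        gnn_explain(model, params, samples[1], steps=25, seed=0)
        for k in params:
            np.testing.assert_array_equal(params[k], before[k])

    def test_motif_edges_weighted_above_background(self, trained_gcn):
        """Edges of the label-determining clique should keep more mask
        weight than off-motif edges, averaged over explained positives."""
        model, params, samples = trained_gcn
        motif_scores, background_scores = [], []
        for s in samples:
            if s.y != 1:
                continue
            probs, _ = model.forward(s.A_norm, s.X, params)
            if probs.argmax() != 1:
                continue
            ex = gnn_explain(model, params, s, lambda_size=0.05,
                             lambda_entropy=0.1, steps=300, lr=0.1, seed=0)
            motif = ex.edge_mask[:MOTIF, :MOTIF][np.triu_indices(MOTIF, 1)]
            mask_off = ex.edge_mask.copy()
            mask_off[:MOTIF, :MOTIF] = 0.0
            off = mask_off[mask_off > 0]
            motif_scores.append(motif[motif > 0].mean())
            if off.size:
                background_scores.append(off.mean())
        assert motif_scores, "no correctly classified positives to explain"
        if background_scores:
            assert np.mean(motif_scores) > np.mean(background_scores)
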