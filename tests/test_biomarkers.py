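"""RLF selection and SpeCo co-occurrence detection."""

import numpy as np
import pandas as pd
import pytest

from connectoml.biomarkers import (
    CooccurrenceMatrix,
    cooccurrence,
    discriminative_pairs,
    majority_pairs,
    rlf_scores,
    rlf_select,
    roi_frequency,
    spectral_partition,
    speco,
)
from connectoml.datamodel import ConnectivityMatrix, ConnectomlError
from connectoml.features import local_column_names


def _local_df(X, n_roi):
    return pd.DataFrame(X, columns=local_column_names(n_roi))


class TestRlfScores:
    def test_label_column_scores_highest(self, rng):
        y = np.array([0, 1] * 20)
        X = rng.standard_normal((40, 2 * 26))
        X[:, 5] = y * 10.0
        scored = rlf_scores(_local_df(X, 2), y)
        best = max(scored, key=lambda p: p.score)
        assert (best.roi_id, best.measure) == (0, _local_df(X, 2).columns[5].split("__")[1])

    def test_constant_column_scores_zero_not_error(self, rng):
        y = np.array([0, 1] * 10)
        X = rng.standard_normal((20, 26))
        X[:, 3] = 7.0
        scored = rlf_scores(_local_df(X, 1), y)
        assert scored[3].score == 0.0

    def test_duplicated_columns_equal_scores(self, rng):
        y = np.array([0, 1] * 10)
        X = rng.standard_normal((20, 26))
        X[:, 1] = X[:, 0]
        scored = rlf_scores(_local_df(X, 1), y)
        assert scored[0].score == pytest.approx(scored[1].score)

    def test_pure_noise_scores_small(self, rng):
        y = np.array([0, 1] * 100)
        X = rng.standard_normal((200, 26))
        scored = rlf_scores(_local_df(X, 1), y)
        # F ~ F(1, n-2) under the null; nothing should look enormous
        assert max(p.score for p in scored) < 15

    def test_shapley_mode_requires_attributor(self, rng):
        y = np.array([0, 1] * 5)
        X = rng.standard_normal((10, 26))
        with pytest.raises(ConnectomlError):
            rlf_scores(_local_df(X, 1), y, method="shapley")

    def test_shapley_mode_with_tree_attributor(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        from connectoml.explain import feature_attribution

        y = np.array([0, 1] * 20)
        X = rng.standard_normal((40, 26))
        X[:, 7] += y * 5.0

        def attributor(X_, y_):
            rf = RandomForestClassifier(n_estimators=20, max_depth=4,
                                        random_state=0).fit(X_, y_)
            return feature_attribution(rf, X_, mode="exact").mean_abs

        scored = rlf_scores(_local_df(X, 1), y, method="shapley",
                            attributor=attributor)
        assert np.argmax([p.score for p in scored]) == 7


class TestRlfSelect:
    def test_exactly_top_m(self, rng):
        y = np.array([0, 1] * 30)
        X = rng.standard_normal((60, 164 * 26))
        scored = rlf_scores(_local_df(X, 164), y)
        assert len(scored) == 4264
        top = rlf_select(scored, top_m=100)
        assert len(top) == 100
        floor = min(p.score for p in top)
        rest = [p.score for p in scored if p not in top]
        assert floor >= max(rest) - 1e-12

    def test_tie_break_lexicographic(self):
        from connectoml.biomarkers import RlfPair

        pairs = [RlfPair(r, m, 1.0) for r in (1, 0) for m in ("b", "a")]
        top = rlf_select(pairs, top_m=2)
        assert [(p.roi_id, p.measure) for p in top] == [(0, "a"), (0, "b")]

    def test_insufficient_pairs_rejected(self):
        from connectoml.biomarkers import RlfPair

        with pytest.raises(ConnectomlError):
            rlf_select([RlfPair(0, "a", 1.0)], top_m=2)


class TestRoiFrequency:
    def test_counts_sum_to_selection_size(self):
        from connectoml.biomarkers import RlfPair

        pairs = [RlfPair(i % 10, f"m{i}", 1.0) for i in range(100)]
        freq = roi_frequency(pairs)
        assert freq.sum() == 100
        assert (freq == 10).all()

    def test_single_roi(self):
        from connectoml.biomarkers import RlfPair

        freq = roi_frequency([RlfPair(4, f"m{i}", 1.0) for i in range(7)])
        assert freq.index.tolist() == [4]
        assert freq.iloc[0] == 7


class TestSpectralPartition:
    def test_two_disconnected_cliques_split_exactly(self):
        W = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        W[i, j] = 0.5
        m = ConnectivityMatrix("s", W, stage="rectified")
        p = spectral_partition(m, k=2, seed=0)
        assert len(set(p[:3])) == 1
        assert len(set(p[3:])) == 1
        assert p[0] != p[3]

    def test_k_equals_n_gives_singletons(self):
        W = np.full((4, 4), 0.3)
        np.fill_diagonal(W, 0.0)
        m = ConnectivityMatrix("s", W, stage="rectified")
        p = spectral_partition(m, k=4, seed=0)
        assert len(set(p)) == 4

    def test_same_seed_identical(self, rng):
        from conftest import random_rectified

        m = random_rectified(12, rng)
        np.testing.assert_array_equal(spectral_partition(m, 3, seed=5),
                                      spectral_partition(m, 3, seed=5))

    def test_zero_matrix_rejected(self):
        m = ConnectivityMatrix("s", np.zeros((4, 4)), stage="rectified")
        with pytest.raises(ConnectomlError):
            spectral_partition(m, k=2)


class TestCooccurrence:
    def test_enumerated_partitions(self):
        # subjects: {AB|C}, {AB|C}, {A|BC}
        parts = [np.array([0, 0, 1]), np.array([0, 0, 1]), np.array([0, 1, 1])]
        cm = cooccurrence(parts, group=1, k=2)
        assert cm.counts[0, 1] == 2
        assert cm.counts[1, 2] == 1
        assert cm.counts[0, 2] == 0
        assert np.all(np.diag(cm.counts) == 3)

    def test_identical_partitions_all_or_nothing(self):
        parts = [np.array([0, 0, 1, 1])] * 5
        cm = cooccurrence(parts, group=0, k=2)
        off = cm.counts[~np.eye(4, dtype=bool)]
        assert set(off.tolist()) <= {0, 5}

    def test_inconsistent_roi_sets_rejected(self):
        with pytest.raises(ConnectomlError):
            cooccurrence([np.array([0, 1]), np.array([0, 1, 1])], 0, 2)


class TestMajorityAndDiscriminative:
    def _cm(self, count, G=10):
        c = np.zeros((3, 3), int)
        c[0, 1] = c[1, 0] = count
        np.fill_diagonal(c, G)
        return CooccurrenceMatrix(counts=c, group=1, group_size=G, k=2)

    def test_inclusive_threshold_rule(self):
        assert (0, 1) in majority_pairs(self._cm(9), 0.90)
        assert (0, 1) not in majority_pairs(self._cm(8), 0.90)

    def test_unanimity_at_theta_one(self):
        assert (0, 1) not in majority_pairs(self._cm(9), 1.0)
        assert (0, 1) in majority_pairs(self._cm(10), 1.0)

    def test_majority_sets_shrink_with_theta(self, rng):
        c = rng.integers(0, 11, size=(6, 6))
        c = np.triu(c, 1)
        c = c + c.T
        np.fill_diagonal(c, 10)
        cm = CooccurrenceMatrix(counts=c, group=0, group_size=10, k=3)
        s90 = majority_pairs(cm, 0.90)
        s95 = majority_pairs(cm, 0.95)
        assert s95 <= s90

    def test_symmetric_difference_tagged(self):
        out = discriminative_pairs({("A", "B")}, {("A", "B"), ("B", "C")})
        assert out == {("B", "C"): "control"}
        assert discriminative_pairs(set(), set()) == {}


class TestSpeco:
    def test_sweep_shape_and_determinism(self, tiny_cohort):
        settings = speco(tiny_cohort, k_range=(2, 3), theta_range=(0.9,),
                         seed=1)
        assert len(settings) == 2
        again = speco(tiny_cohort, k_range=(2, 3), theta_range=(0.9,), seed=1)
        for a, b in zip(settings, again):
            assert a.informative == b.informative

    def test_default_sweep_has_eight_settings(self, tiny_cohort):
        assert len(speco(tiny_cohort, seed=0)) == 8

    def test_planted_pairs_recovered(self, strong_cohort):
        cohort, truth = strong_cohort
        settings = speco(cohort, seed=0)
        planted = {tuple(sorted(p)) for p in truth.differing_pairs}
        best = max(
            len(planted & {tuple(sorted(p)) for p in s.informative}) / len(planted)
            for s in settings
        )
        assert best >= 0.8
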