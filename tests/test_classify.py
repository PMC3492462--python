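"""Gini ranking, tie-break KNN, cross-validation and screening metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.neighbors import KNeighborsClassifier

from _oracles import brute_force_stump_gini
from radpanel import classify as cl
from radpanel.design import CLASS_ORDER


class TestGiniNode:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0), 0.0),
        ((5, 5), 0.5),
        ((1, 1, 1, 1), 0.75),
        ((3, 1), 1 - (0.75 ** 2 + 0.25 ** 2)),
    ])
    def test_examples(self, counts, expected):
        assert cl.gini_node(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            cl.gini_node([0, 0])
        with pytest.raises(ValueError):
            cl.gini_node([-1, 2])

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=8).filter(
        lambda c: sum(c) > 0))
    def test_bounds_and_purity(self, counts):
        g = cl.gini_node(counts)
        assert 0.0 <= g <= 1.0
        if sum(1 for c in counts if c > 0) == 1:
            assert g == 0.0


class TestPairwiseGini:
    def test_perfect_separation(self):
        s = cl.pairwise_gini([1, 2, 10, 11], ["N", "N", "R", "R"])
        assert s.impurity == 0.0
        assert 2 < s.split_threshold < 10

    def test_interleaved_input_order(self):
        s = cl.pairwise_gini([1, 10, 2, 11], ["N", "R", "N", "R"])
        assert s.impurity == 0.0

    def test_single_distinct_value_gives_unsplit_gini(self):
        s = cl.pairwise_gini([3.0, 3.0, 3.0, 3.0], ["N", "N", "R", "R"])
        assert s.impurity == pytest.approx(0.5)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            cl.pairwise_gini([1, 2], ["N", "N"])

    def test_smallest_threshold_on_ties(self):
        # both gaps give impurity 0.5; the smaller midpoint must win
        s = cl.pairwise_gini([0.0, 1.0, 2.0, 3.0], ["N", "R", "N", "R"])
        oracle = brute_force_stump_gini([0, 1, 2, 3], ["N", "R", "N", "R"])
        assert s.impurity == pytest.approx(oracle)
        assert s.split_threshold == pytest.approx(0.5)

    @given(st.integers(0, 200))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        v = np.round(rng.normal(0, 1, n), 2)
        y = rng.choice(["N", "R"], n)
        if len(set(y)) < 2:
            y[0], y[1] = "N", "R"
        s = cl.pairwise_gini(v, y)
        assert s.impurity == pytest.approx(brute_force_stump_gini(v, y), abs=1e-12)


class TestMarkerOrdering:
    def test_first_pair_priority(self):
        # X separates (N, R) perfectly; Y separates (N, L) perfectly
        X = pd.DataFrame({
            "X": [0, 0, 10, 10, 1, 2],
            "Y": [0, 0, 3, 4, 10, 10],
        })
        y = ["N", "N", "R", "R", "L", "L"]
        order = cl.order_markers(X, y, pair_order=(("N", "R"), ("N", "L")))
        assert order.order == ("X", "Y")
        assert order.provenance["X"] == (("N", "R"), 1)

    def test_dominant_marker_appears_once_first(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({
            "best": np.repeat([0.0, 5.0, 10.0, 15.0], 3),
            "noise": rng.normal(size=12),
        })
        y = np.repeat(["N", "R", "L", "RL"], 3)
        order = cl.order_markers(X, y)
        assert order.order[0] == "best"
        assert len(order.order) == 2

    def test_order_is_deterministic_permutation(self, marker_dataset):
        X, y = marker_dataset
        a = cl.order_markers(X, y)
        b = cl.order_markers(X, y)
        assert a.order == b.order
        assert sorted(a.order) == sorted(X.columns)
        assert set(a.provenance) == set(X.columns)

    def test_transform_reorders_columns(self, marker_dataset):
        X, y = marker_dataset
        ranker = cl.GiniMarkerRanker().fit(X, y)
        assert list(ranker.transform(X).columns) == list(ranker.order_)


class TestTieBreakKNN:
    def test_k1_returns_exact_match_label(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        y = np.array(["N", "R", "L"])
        pred = cl.knn_predict(X, y, [[5.0, 5.0]], k=1)
        assert pred[0] == "R"

    def test_unanimous_neighbors(self):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        y = np.array(["N"] * 5 + ["R"] * 5)
        pred = cl.knn_predict(X, y, [[0.4, 0.1]], k=5)
        assert pred[0] == "N"

    def test_vote_tie_broken_by_mean_distance(self):
        # k=5 over a 2-2-1 vote: N neighbours nearer than R neighbours
        X = np.array([[0.0], [0.2], [3.0], [3.2], [8.0]])
        y = np.array(["N", "N", "R", "R", "L"])
        pred = cl.knn_predict(X, y, [[0.1]], k=5, scale=False)
        assert pred[0] == "N"

    def test_class_order_breaks_symmetric_tie(self):
        # perfectly symmetric 2-2 vote with 1 spectator: falls to class order
        X = np.array([[-1.0], [-2.0], [1.0], [2.0], [50.0]])
        y = np.array(["L", "L", "R", "R", "RL"])
        pred = cl.knn_predict(X, y, [[0.0]], k=5, scale=False)
        assert pred[0] == "R"  # R precedes L in the canonical order

    def test_matches_sklearn_on_tie_free_fixture(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.choice(list(CLASS_ORDER), 30)
        test = rng.normal(size=(20, 4))
        ours = cl.knn_predict(X, y, test, k=1, scale=False)
        ref = KNeighborsClassifier(n_neighbors=1).fit(X, y).predict(test)
        assert (ours == ref).all()

    def test_matches_brute_force_vote(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.choice(list(CLASS_ORDER), 50)
        test = rng.normal(size=(15, 3))
        ours = cl.knn_predict(X, y, test, k=5, scale=False)
        for x, got in zip(test, ours):
            d = np.linalg.norm(X - x, axis=1)
            nn = np.argsort(d, kind="stable")[:5]
            votes = pd.Series(y[nn]).value_counts()
            top = votes[votes == votes.max()].index
            if len(top) == 1:
                assert got == top[0]
            else:
                assert got in set(top)

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError):
            cl.knn_predict(np.zeros((3, 1)), ["N", "R", "L"], [[0.0]], k=5)


class TestCrossValidation:
    def test_confusion_total_counts(self, marker_dataset):
        X, y = marker_dataset
        res = cl.cross_validate(X, y, config=cl.ClassifierConfig(seed=1))
        assert res.confusion.to_numpy().sum() == 10 * 40
        assert (res.confusion.sum(axis=1) == 100).all()  # 10 repeats x 10/class

    def test_seed_determinism(self, marker_dataset):
        X, y = marker_dataset
        a = cl.cross_validate(X, y, config=cl.ClassifierConfig(seed=3))
        b = cl.cross_validate(X, y, config=cl.ClassifierConfig(seed=3))
        assert a.accuracy == b.accuracy
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_accuracy_between_chance_and_one(self, marker_dataset):
        X, y = marker_dataset
        res = cl.cross_validate(
            X, y, config=cl.ClassifierConfig(n_repeats=2, seed=0)
        )
        assert 0.25 < res.accuracy <= 1.0

    def test_empty_marker_subset_rejected(self, marker_dataset):
        X, y = marker_dataset
        with pytest.raises(ValueError):
            cl.cross_validate(X, y, marker_subset=[])

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            cl.ClassifierConfig(k_neighbors=4)

    def test_donor_grouped_folds_respect_groups(self, marker_dataset):
        X, y = marker_dataset
        groups = [d for d, _, _ in X.index]
        cfg = cl.ClassifierConfig(donor_grouped=True, n_folds=5, n_repeats=1)
        res = cl.cross_validate(X, y, config=cfg, groups=groups)
        assert res.confusion.to_numpy().sum() == 40


class TestAccuracyCurve:
    def test_single_marker_consistency(self, marker_dataset):
        X, y = marker_dataset
        order = cl.order_markers(X, y)
        cfg = cl.ClassifierConfig(n_repeats=2, seed=9)
        curve = cl.accuracy_curve(X, y, order, cfg)
        solo = cl.cross_validate(X, y, [order.order[0]], cfg)
        assert curve.loc[0, "accuracy"] == pytest.approx(solo.accuracy)
        assert len(curve) == X.shape[1]

    def test_curve_records_best_size(self, marker_dataset):
        X, y = marker_dataset
        order = cl.order_markers(X, y)
        curve = cl.accuracy_curve(X, y, order, cl.ClassifierConfig(n_repeats=2))
        best = curve.attrs["best_size"]
        assert curve.loc[best - 1, "accuracy"] == curve["accuracy"].max()


class TestDiagnosticScreening:
    def test_identity_matrix_perfect_metrics(self):
        conf = pd.DataFrame(np.eye(4, dtype=int) * 10,
                            index=CLASS_ORDER, columns=CLASS_ORDER)
        report = cl.diagnostic_screening(conf)
        assert (report.metrics[["sensitivity", "specificity", "ppv", "npv"]]
                .to_numpy() == 1.0).all()
        assert report.overall_accuracy == 1.0

    def test_uniform_matrix_symmetry(self):
        conf = pd.DataFrame(np.full((4, 4), 5), index=CLASS_ORDER,
                            columns=CLASS_ORDER)
        report = cl.diagnostic_screening(conf)
        np.testing.assert_allclose(report.metrics["sensitivity"], 0.25)
        np.testing.assert_allclose(report.metrics["ppv"], 0.25)

    def test_matches_two_by_two_collapse_oracle(self):
        M = np.array([[8, 1, 1, 0], [2, 7, 0, 1], [0, 1, 9, 0], [1, 1, 1, 7]])
        conf = pd.DataFrame(M, index=CLASS_ORDER, columns=CLASS_ORDER)
        report = cl.diagnostic_screening(conf)
        total = M.sum()
        for i, c in enumerate(CLASS_ORDER):
            tp = M[i, i]
            fn = M[i].sum() - tp
            fp = M[:, i].sum() - tp
            tn = total - tp - fn - fp
            row = report.metrics.loc[c]
            assert row["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert row["specificity"] == pytest.approx(tn / (tn + fp))
            assert row["ppv"] == pytest.approx(tp / (tp + fp))
            assert row["npv"] == pytest.approx(tn / (tn + fn))
        assert report.overall_accuracy == pytest.approx(np.trace(M) / total)

    def test_zero_column_flagged(self):
        M = np.array([[10, 0], [5, 0]])
        conf = pd.DataFrame(M, index=["N", "R"], columns=["N", "R"])
        report = cl.diagnostic_screening(conf)
        assert report.metrics.loc["R", "flag"] == "degenerate"
        assert np.isnan(report.metrics.loc["R", "ppv"])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            cl.diagnostic_screening(pd.DataFrame(np.zeros((2, 3))))
        with pytest.raises(ValueError):
            cl.diagnostic_screening(
                pd.DataFrame(np.zeros((2, 2)), index=["N", "R"], columns=["N", "R"])
            )
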