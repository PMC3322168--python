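"""Naive Bayes, cross-validation, ROC/AUC, kappa — with external oracles."""

import numpy as np
import pandas as pd
import pytest

from speechgraph import (
    FeatureMatrix,
    GaussianNaiveBayes,
    cohen_kappa,
    cross_validate,
    roc_auc,
    run_comparison,
    sens_spec,
)
from speechgraph.classify import roc_points
from speechgraph.errors import InsufficientDataError, UnknownFeatureError

import oracles


def fm(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return FeatureMatrix(
        X=X, y=np.asarray(y), feature_names=[f"f{i}" for i in range(X.shape[1])],
        subject_ids=[str(i) for i in range(len(y))],
    )


class TestNaiveBayes:
    def test_moments_from_training_rows(self):
        model = GaussianNaiveBayes().fit(np.array([[0.0], [0.0], [1.0], [1.0]]),
                                         np.array([0, 0, 1, 1]))
        assert model.means_[0, 0] == 0.0 and model.means_[1, 0] == 1.0
        assert (model.sds_ > 0).all()  # floored, not degenerate

    def test_priors_are_class_frequencies(self):
        X = np.zeros((8, 1))
        y = np.array([0] * 6 + [1] * 2)
        X[y == 1] = 1.0
        model = GaussianNaiveBayes().fit(X, y)
        assert np.exp(model.log_priors_) == pytest.approx([0.75, 0.25])

    def test_midpoint_posterior_is_half(self):
        X = np.array([[0.0], [0.2], [1.0], [0.8]])
        y = np.array([0, 0, 1, 1])
        model = GaussianNaiveBayes().fit(X, y)
        assert model.score(np.array([[0.5]]))[0] == pytest.approx(0.5)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = GaussianNaiveBayes().fit(rng.normal(size=(20, 3)),
                                         np.repeat([0, 1], 10))
        probs = model.predict_proba(rng.normal(size=(7, 3)))
        assert probs.sum(axis=1) == pytest.approx(np.ones(7))

    def test_confident_at_class_mean_when_separated(self):
        X = np.concatenate([np.random.default_rng(2).normal(0, 0.1, (10, 1)),
                            np.random.default_rng(3).normal(10, 0.1, (10, 1))])
        y = np.repeat([0, 1], 10)
        model = GaussianNaiveBayes().fit(X, y)
        assert model.score(np.array([[10.0]]))[0] > 0.99
        assert model.score(np.array([[0.0]]))[0] < 0.01

    def test_small_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            GaussianNaiveBayes().fit(np.zeros((3, 1)), np.array([0, 0, 1]))

    def test_matches_sklearn_posteriors(self):
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3)) + np.repeat([0, 1], 100)[:, None]
        y = np.repeat([0, 1], 100)
        ours = GaussianNaiveBayes().fit(X, y)
        theirs = sklearn.GaussianNB().fit(X, y)
        Xq = rng.normal(size=(50, 3))
        np.testing.assert_allclose(
            ours.score(Xq), theirs.predict_proba(Xq)[:, 1], atol=0.02
        )


class TestCrossValidate:
    def test_loo_scores_every_subject(self):
        rng = np.random.default_rng(5)
        features = fm(rng.normal(size=16), np.repeat([0, 1], 8))
        scores = cross_validate(features)
        assert scores.shape == (16,) and not np.isnan(scores).any()

    def test_separable_feature_scores_on_correct_side(self):
        X = np.concatenate([np.zeros(8), np.ones(8)]) + \
            np.random.default_rng(6).normal(scale=0.01, size=16)
        features = fm(X, np.repeat([0, 1], 8))
        scores = cross_validate(features)
        assert (scores[8:] > 0.5).all() and (scores[:8] < 0.5).all()

    def test_stratified_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        features = fm(rng.normal(size=(20, 2)), np.repeat([0, 1], 10))
        s1 = cross_validate(features, scheme="stratified", seed=42)
        s2 = cross_validate(features, scheme="stratified", seed=42)
        s3 = cross_validate(features, scheme="stratified", seed=43)
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, s3)

    def test_balanced_training_folds_have_equal_class_counts(self):
        from speechgraph.classify import _balance_training_mask

        y = np.array([0] * 12 + [1] * 8)
        mask = np.ones(20, dtype=bool)
        mask[15] = False  # held-out subject of class 1
        balanced = _balance_training_mask(y, mask, fold_index=15)
        assert (y[balanced] == 0).sum() == (y[balanced] == 1).sum() == 7


class TestRoc:
    def test_perfect_and_inverted_ranking(self):
        labels = [1, 1, 0, 0]
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.2], labels)
        assert auc == 1.0
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.2], [0, 0, 1, 1])
        assert auc == 0.0

    def test_curve_is_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(8)
        points = roc_points(rng.random(30), rng.integers(0, 2, 30) | np.array([1] + [0] * 29))
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        xs, ys = zip(*points)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))

    def test_auc_equals_mann_whitney_fraction(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.8], size=n)  # ties included
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(oracles.mann_whitney_auc(scores, labels))

    def test_auc_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(10)
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25) | np.array([1] + [0] * 24)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == a2

    def test_matches_sklearn_auc(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        scores = rng.choice([0.2, 0.4, 0.4, 0.9], size=40)
        labels = np.array([1] * 15 + [0] * 25)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(metrics.roc_auc_score(labels, scores))


class TestOperatingPoint:
    def test_perfect_scores(self):
        assert sens_spec([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0]) == (1.0, 1.0)

    def test_all_predicted_positive(self):
        sens, spec = sens_spec([0.9, 0.9, 0.9, 0.9], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 0.0

    def test_sixteen_per_group_operating_point(self):
        # TP=15, FN=1, TN=15, FP=1 -> 0.938/0.938
        scores = [0.9] * 15 + [0.1] + [0.1] * 15 + [0.9]
        labels = [1] * 16 + [0] * 16
        sens, spec = sens_spec(scores, labels)
        assert round(sens, 3) == round(spec, 3) == 0.938


class TestKappa:
    def test_identical_raters(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_hand_computed_table(self):
        # agreement table (3,1;1,3): p_o=0.75, p_e=0.5 -> kappa=0.5
        pred = [1, 1, 1, 0, 0, 0, 0, 1]
        true = [1, 1, 1, 1, 0, 0, 0, 0]
        assert cohen_kappa(pred, true) == pytest.approx(0.5)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(12)
        pred = rng.integers(0, 2, 4000)
        true = rng.integers(0, 2, 4000)
        assert abs(cohen_kappa(pred, true)) < 0.05


class TestRunComparison:
    @staticmethod
    def table(sep=6.0, n=10, seed=13):
        rng = np.random.default_rng(seed)
        rows = []
        for group, offset in (("schizophrenic", 0.0), ("manic", sep)):
            for i in range(n):
                rows.append({
                    "subject_id": f"{group}_{i}", "group": group,
                    "N_per_word": rng.normal(offset, 1.0),
                    "E_per_word": rng.normal(offset, 1.0),
                    "ATD_per_word": rng.normal(offset, 1.0),
                })
        return pd.DataFrame(rows)

    def test_separated_groups_classified(self):
        report = run_comparison(self.table(), "SxM")
        assert report.auc >= 0.9
        assert report.features == ["N_per_word", "E_per_word", "ATD_per_word"]
        assert report.kappa > 0.8

    def test_unknown_feature_rejected(self):
        with pytest.raises(UnknownFeatureError):
            run_comparison(self.table(), "SxM", features=["nope"])

    def test_single_group_rejected(self):
        table = self.table()
        with pytest.raises(ValueError):
            run_comparison(table[table["group"] == "manic"], "SxM")

    def test_unknown_comparison_rejected(self):
        with pytest.raises(ValueError):
            run_comparison(self.table(), "XxY")

    def test_report_roundtrips_to_json(self):
        import json

        report = run_comparison(self.table(), "SxM")
        payload = json.loads(report.to_json())
        assert payload["comparison"] == "SxM"
        assert 0.0 <= payload["auc"] <= 1.0
        assert payload["positive_label"] == "schizophrenic"

    def test_pluggable_classifier_contract(self):
        class MeanThreshold:
            def fit(self, X, y):
                self.cut = X[:, 0].mean()
                self.hi = X[y == 1, 0].mean() > X[y == 0, 0].mean()
                return self

            def score(self, X):
                raw = (X[:, 0] > self.cut).astype(float)
                return raw if self.hi else 1 - raw

        report = run_comparison(
            self.table(), "SxM", classifier_factory=MeanThreshold
        )
        assert report.auc >= 0.9
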