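"""Stratified-split protocol and the four score-based classifiers."""

import numpy as np
import pytest

from fdgm.classification import (
    ClassifierSpec,
    GaussianNaiveBayes,
    UsageError,
    default_specs,
    evaluate_protocol,
    split_stratified,
    train_classifier,
)
from fdgm.landmark_io import ValidationError


def clustered_scores(rng, centres, n_per_class, sd=1.0):
    centres = np.asarray(centres, float)
    scores = np.vstack(
        [rng.normal(c, sd, size=(n_per_class, centres.shape[1])) for c in centres]
    )
    labels = np.repeat([f"c{i}" for i in range(len(centres))], n_per_class)
    return scores, labels


class TestSplitStratified:
    def test_exact_70_30_counts(self):
        labels = np.repeat(["a", "b", "c"], 30)
        train, test = split_stratified(labels, 0.7, seed=0)
        for c in "abc":
            assert np.sum(labels[train] == c) == 21
            assert np.sum(labels[test] == c) == 9

    def test_study_class_sizes_rounding(self):
        # class sizes 29/30/30 at fraction 0.7 -> train 20/21/21
        labels = np.array(["a"] * 29 + ["b"] * 30 + ["c"] * 30)
        train, _ = split_stratified(labels, 0.7, seed=5)
        counts = [np.sum(labels[train] == c) for c in "abc"]
        assert counts == [20, 21, 21]

    def test_deterministic_given_seed(self):
        labels = np.repeat(["a", "b"], 10)
        s1 = split_stratified(labels, 0.7, seed=42)
        s2 = split_stratified(labels, 0.7, seed=42)
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])

    def test_partition_properties(self, rng):
        labels = rng.choice(["a", "b", "c"], size=50)
        train, test = split_stratified(labels, 0.6, seed=3)
        assert set(train).isdisjoint(test)
        assert len(train) + len(test) == 50

    def test_both_sides_nonempty_even_for_tiny_classes(self):
        labels = np.array(["a", "a", "b", "b", "b"])
        train, test = split_stratified(labels, 0.9, seed=0)
        for c in "ab":
            assert np.sum(labels[train] == c) >= 1
            assert np.sum(labels[test] == c) >= 1

    def test_singleton_class_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            split_stratified(np.array(["a", "b", "b"]), 0.7, seed=0)

    def test_fraction_validated(self):
        with pytest.raises(UsageError):
            split_stratified(np.repeat(["a", "b"], 5), 1.2, seed=0)


class TestGaussianNaiveBayes:
    def test_equidistant_point_gets_half_half_posterior(self):
        # equal priors, equal variances, query halfway between the means
        x = np.array([[-1.0], [-3.0], [1.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        nb = GaussianNaiveBayes().fit(x, y)
        proba = nb.predict_proba([[0.0]])
        np.testing.assert_allclose(proba, [[0.5, 0.5]], atol=1e-12)

    def test_posteriors_sum_to_one(self, rng):
        x, y = clustered_scores(rng, [[0, 0, 0], [2, 1, 0], [1, 0, 2]], 10)
        nb = GaussianNaiveBayes().fit(x, y)
        proba = nb.predict_proba(rng.normal(size=(20, 3)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_two_class_1d_matches_bayes_formula_oracle(self):
        # priors 0.5/0.5, unit variances, means 0 and 2, query at 0:
        # posterior(class 1) = phi(0;0,1) / (phi(0;0,1) + phi(0;2,1))
        def density(x, mean):
            return np.exp(-0.5 * (x - mean) ** 2) / np.sqrt(2 * np.pi)

        nb = GaussianNaiveBayes()
        nb.classes_ = np.array(["a", "b"])
        nb.means_ = np.array([[0.0], [2.0]])
        nb.variances_ = np.array([[1.0], [1.0]])
        nb.log_priors_ = np.log([0.5, 0.5])
        oracle = density(0.0, 0.0) / (density(0.0, 0.0) + density(0.0, 2.0))
        assert nb.predict_proba([[0.0]])[0, 0] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_variance_floor(self):
        x = np.column_stack([np.ones(6), np.r_[0.0, 0.1, -0.1, 5.0, 5.1, 4.9]])
        y = np.repeat(["a", "b"], 3)
        nb = GaussianNaiveBayes().fit(x, y)
        assert np.all(nb.variances_ >= nb.variance_floor)
        assert np.all(np.isfinite(nb.predict_proba([[1.0, 2.5]])))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValidationError, match="single class"):
            GaussianNaiveBayes().fit(np.zeros((4, 2)), np.repeat(["a"], 4))


class TestTrainClassifier:
    @pytest.mark.parametrize("name", ["NB", "SVM", "RF", "GLM"])
    def test_separable_training_data_classified(self, rng, name):
        x, y = clustered_scores(rng, [[0, 0, 0], [10, 0, 0], [0, 10, 0]], 12, sd=0.5)
        spec = ClassifierSpec(name, {"n_estimators": 50} if name == "RF" else {})
        model = train_classifier(spec, x, y, seed=0)
        assert np.mean(model.predict(x) == y) >= 0.95

    def test_hyperparameter_validation(self):
        with pytest.raises(UsageError):
            ClassifierSpec("SVM", {"C": -1})
        with pytest.raises(UsageError):
            ClassifierSpec("GLM", {"l1_ratio": 2.0})
        with pytest.raises(UsageError):
            ClassifierSpec("QDA")


class TestEvaluateProtocol:
    def test_separable_clusters_reach_high_accuracy(self, rng):
        # class-mean distance 10x the within-class sd
        x, y = clustered_scores(rng, [[0, 0, 0], [10, 0, 0], [0, 10, 0]], 30, sd=1.0)
        specs = [
            ClassifierSpec("NB"),
            ClassifierSpec("SVM"),
            ClassifierSpec("RF", {"n_estimators": 100}),
            ClassifierSpec("GLM", {"cv_folds": 3}),
        ]
        report = evaluate_protocol(x, y, specs=specs, reps=5, seed0=11)
        for name in report.classifier_names:
            assert report.mean_accuracy(name) >= 0.95

    def test_permuted_labels_give_chance_level(self, rng):
        x, y = clustered_scores(rng, [[0, 0, 0], [10, 0, 0], [0, 10, 0]], 30, sd=1.0)
        y_perm = rng.permutation(y)
        specs = [ClassifierSpec("NB"), ClassifierSpec("SVM")]
        report = evaluate_protocol(x, y_perm, specs=specs, reps=10, seed0=2)
        for name in report.classifier_names:
            assert abs(report.mean_accuracy(name) - 1 / 3) < 0.20

    def test_report_is_deterministic(self, rng):
        x, y = clustered_scores(rng, [[0, 0, 0], [3, 0, 0]], 15)
        specs = [ClassifierSpec("NB"), ClassifierSpec("RF", {"n_estimators": 25})]
        r1 = evaluate_protocol(x, y, specs=specs, reps=4, seed0=9)
        r2 = evaluate_protocol(x, y, specs=specs, reps=4, seed0=9)
        for name in r1.classifier_names:
            np.testing.assert_array_equal(r1.accuracies[name], r2.accuracies[name])

    def test_report_statistics_consistent(self, rng):
        x, y = clustered_scores(rng, [[0, 0, 0], [2, 0, 0]], 15)
        report = evaluate_protocol(x, y, specs=[ClassifierSpec("NB")], reps=6, seed0=1)
        acc = report.accuracies["NB"]
        assert np.all((0 <= acc) & (acc <= 1))
        assert report.mean_accuracy("NB") == pytest.approx(acc.mean())
        assert report.sd_accuracy("NB") == pytest.approx(acc.std(ddof=1), abs=1e-12)
        assert acc.min() <= report.mean_accuracy("NB") <= acc.max()

    def test_default_specs_cover_all_four(self):
        assert [s.name for s in default_specs()] == ["NB", "SVM", "RF", "GLM"]
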