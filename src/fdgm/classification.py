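"""Score-based classification protocol.

Species are predicted from the first K = 3 principal component scores
with four classifiers — Gaussian naive Bayes, an RBF-kernel support
vector machine (one-vs-one across class pairs), a random forest, and a
multinomial elastic-net GLM.  Performance is the plain test-set
accuracy under a stratified 70:30 train/test split repeated 20 times;
the report carries each classifier's mean accuracy and sample standard
deviation over the replicates.  All randomness (splits, forest
bootstraps, CV folds) flows from explicit integer seeds, so a report is
reproducible bit-for-bit.

Naive Bayes is implemented here directly from the Bayes posterior with
Gaussian class-conditional densities: the posterior contract (exact
normalisation, closed-form two-class case) is part of this module's
tested surface.  The SVM, forest and GLM are scikit-learn estimators
behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .landmark_io import ValidationError

VARIANCE_FLOOR = 1e-9


class UsageError(ValueError):
    pass


@dataclass
class ClassifierSpec:
    """Name + hyperparameters of one classifier in the protocol."""

    name: str  # one of NB, SVM, RF, GLM
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("NB", "SVM", "RF", "GLM"):
            raise UsageError(f"unknown classifier {self.name!r}")
        hp = self.hyperparameters
        if self.name == "SVM":
            hp.setdefault("C", 1.0)
            hp.setdefault("gamma", "scale")
            if hp["C"] <= 0:
                raise UsageError("SVM cost C must be positive")
            if isinstance(hp["gamma"], (int, float)) and hp["gamma"] <= 0:
                raise UsageError("SVM gamma must be positive")
        elif self.name == "RF":
            hp.setdefault("n_estimators", 500)
            hp.setdefault("max_features", "sqrt")
            if hp["n_estimators"] < 1:
                raise UsageError("RF needs at least one tree")
        elif self.name == "GLM":
            hp.setdefault("l1_ratio", 0.5)
            hp.setdefault("Cs", 5)
            hp.setdefault("cv_folds", 5)
            if not (0 <= hp["l1_ratio"] <= 1):
                raise UsageError("elastic-net mixing l1_ratio must be in [0, 1]")


def default_specs() -> list[ClassifierSpec]:
    return [ClassifierSpec("NB"), ClassifierSpec("SVM"), ClassifierSpec("RF"), ClassifierSpec("GLM")]


@dataclass
class ClassificationReport:
    """Replicated-split accuracies per classifier (mean and sample sd)."""

    classifier_names: list[str]
    accuracies: dict[str, np.ndarray]  # per classifier, length reps
    seed0: int
    reps: int
    train_fraction: float

    def mean_accuracy(self, name: str) -> float:
        return float(self.accuracies[name].mean())

    def sd_accuracy(self, name: str) -> float:
        return float(self.accuracies[name].std(ddof=1))

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            name: {
                "mean_accuracy": self.mean_accuracy(name),
                "sd_accuracy": self.sd_accuracy(name),
            }
            for name in self.classifier_names
        }


class GaussianNaiveBayes:
    """Gaussian naive Bayes classifier built from the Bayes posterior.

    Class-conditional densities are products of per-feature Gaussians
    with class-specific means and variances (maximum-likelihood, i.e.
    divisor n_c); priors are empirical class frequencies.  A variance
    floor guards against constant feature columns.
    """

    def __init__(self, variance_floor: float = VARIANCE_FLOOR) -> None:
        self.variance_floor = variance_floor

    def fit(self, x: np.ndarray, y: Sequence) -> "GaussianNaiveBayes":
        x = np.asarray(x, float)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(y.tolist())))
        if self.classes_.size < 2:
            raise ValidationError("training set contains a single class")
        self.means_ = np.vstack([x[y == c].mean(axis=0) for c in self.classes_])
        self.variances_ = np.vstack([x[y == c].var(axis=0) for c in self.classes_])
        self.variances_ = np.maximum(self.variances_, self.variance_floor)
        self.log_priors_ = np.log(
            np.array([np.mean(y == c) for c in self.classes_])
        )
        return self

    def _joint_log_likelihood(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        ll = np.empty((x.shape[0], self.classes_.size))
        for j in range(self.classes_.size):
            var = self.variances_[j]
            ll[:, j] = self.log_priors_[j] - 0.5 * np.sum(
                np.log(2 * np.pi * var) + (x - self.means_[j]) ** 2 / var, axis=1
            )
        return ll

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        ll = self._joint_log_likelihood(x)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(x), axis=1)]


def make_classifier(spec: ClassifierSpec, seed: int):
    """Instantiate an unfitted classifier from its spec and a seed."""
    hp = spec.hyperparameters
    if spec.name == "NB":
        return GaussianNaiveBayes()
    if spec.name == "SVM":
        # SVC is natively one-vs-one across class pairs.
        return SVC(C=hp["C"], kernel="rbf", gamma=hp["gamma"], random_state=seed)
    if spec.name == "RF":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            max_features=hp["max_features"],
            random_state=seed,
        )
    if spec.name == "GLM":
        return LogisticRegressionCV(
            solver="saga",
            l1_ratios=[hp["l1_ratio"]],
            Cs=hp["Cs"],
            cv=StratifiedKFold(n_splits=hp["cv_folds"], shuffle=True, random_state=seed),
            scoring="accuracy",
            max_iter=10000,
            tol=1e-4,
            random_state=seed,
            use_legacy_attributes=False,
        )
    raise UsageError(f"unknown classifier {spec.name!r}")


def train_classifier(spec: ClassifierSpec, train_scores: np.ndarray, train_labels, seed: int = 0):
    """Fit one classifier on training scores; returns the fitted model."""
    train_scores = np.asarray(train_scores, float)
    train_labels = np.asarray(train_labels)
    classes, counts = np.unique(train_labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training set contains a single class")
    if spec.name == "GLM":
        # CV folds cannot exceed the smallest training class.
        folds = int(min(spec.hyperparameters["cv_folds"], counts.min()))
        spec = ClassifierSpec("GLM", {**spec.hyperparameters, "cv_folds": max(folds, 2)})
    model = make_classifier(spec, seed)
    model.fit(train_scores, train_labels)
    return model


def split_stratified(
    labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test split.

    Per class c with n_c members the training count is
    round(train_fraction * n_c), clamped to [1, n_c - 1] so both sides
    see every class; members are chosen uniformly at random from the
    seeded generator.  Returns (train_indices, test_indices), each
    sorted, disjoint, with union covering all indices.
    """
    if not (0 < train_fraction < 1):
        raise UsageError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == c)
        n_c = members.size
        if n_c < 2:
            raise ValidationError(
                f"class {c!r} has {n_c} member(s); need at least 2 to split"
            )
        n_train = int(np.floor(train_fraction * n_c + 0.5))
        n_train = min(max(n_train, 1), n_c - 1)
        perm = rng.permutation(members)
        train_idx.append(np.sort(perm[:n_train]))
        test_idx.append(np.sort(perm[n_train:]))
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def evaluate_protocol(
    scores: np.ndarray,
    labels,
    specs: list[ClassifierSpec] | None = None,
    reps: int = 20,
    train_fraction: float = 0.7,
    seed0: int = 0,
) -> ClassificationReport:
    """Run the replicated stratified-split protocol.

    Replicate r uses the split drawn with seed ``seed0 + r``; the same
    split is shared by every classifier within a replicate so the
    comparison is paired.  Accuracy is the plain fraction of correct
    test predictions.
    """
    if specs is None:
        specs = default_specs()
    if reps < 2:
        raise UsageError("need at least 2 replicates for a standard deviation")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    accuracies = {spec.name: np.empty(reps) for spec in specs}
    for r in range(reps):
        split_seed = seed0 + r
        train_idx, test_idx = split_stratified(labels, train_fraction, seed=split_seed)
        train_labels = labels[train_idx]
        if len(set(train_labels.tolist())) < len(set(labels.tolist())):
            raise ValidationError(
                f"replicate with seed {split_seed}: training set lacks a class"
            )
        for spec in specs:
            model_seed = (seed0 * 100003 + 1009 * r) % (2**31 - 1)
            model = train_classifier(spec, scores[train_idx], train_labels, seed=model_seed)
            predicted = model.predict(scores[test_idx])
            accuracies[spec.name][r] = float(np.mean(predicted == labels[test_idx]))
    return ClassificationReport(
        classifier_names=[s.name for s in specs],
        accuracies=accuracies,
        seed0=seed0,
        reps=reps,
        train_fraction=train_fraction,
    )
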