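"""Three classifiers behind a common train/predict contract.

DLDA (diagonal linear discriminant analysis) is implemented from scratch;
the decision-forest (``rf``) and maximum-margin (``svm``) learners are thin
adapters around scikit-learn with seeds exposed for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .feature_matrix import FeatureValueMatrix

CLASSIFIER_KINDS = ("dlda", "rf", "svm")
_VARIANCE_FLOOR_FACTOR = 1e-8


@dataclass
class DLDAModel:
    """Per-class feature means and pooled per-feature variances."""

    feature_ids: tuple
    classes: tuple          # label order, GP first (tie-break winner)
    means: np.ndarray       # (n_classes, n_features)
    variances: np.ndarray   # (n_features,)


def train_dlda(X: FeatureValueMatrix, y) -> DLDAModel:
    """Fit class means and pooled within-class variances.

    Zero pooled variances are floored to 1e-8 x (max variance) so constant
    features cannot produce infinite discriminant scores.
    """
    y = np.asarray(y, dtype=object)
    classes = ("GP", "PP")
    for k in classes:
        if np.sum(y == k) < 2:
            raise ValueError(f"train_dlda requires >= 2 samples of class {k}")
    V = X.values
    n = V.shape[1]
    means = np.vstack([V[:, y == k].mean(axis=1) for k in classes])
    ss = sum(((V[:, y == k] - means[i][:, None]) ** 2).sum(axis=1) for i, k in enumerate(classes))
    variances = ss / (n - len(classes))
    if np.any(variances <= 0):
        floor = _VARIANCE_FLOOR_FACTOR * max(float(variances.max()), 1.0)
        n_floored = int(np.sum(variances <= 0))
        variances = np.where(variances <= 0, floor, variances)
        warnings.warn(f"floored {n_floored} zero pooled variance(s) in DLDA", stacklevel=2)
    return DLDAModel(X.feature_ids, classes, means, variances)


def dlda_scores(model: DLDAModel, X: FeatureValueMatrix) -> np.ndarray:
    """Diagonal Gaussian discriminant distances, shape (n_classes, n_samples)."""
    if X.feature_ids != model.feature_ids:
        raise ValueError("feature ids of test matrix do not match the trained model")
    V = X.values
    return np.vstack(
        [
            (((V - mu[:, None]) ** 2) / model.variances[:, None]).sum(axis=0)
            for mu in model.means
        ]
    )


def predict_dlda(model: DLDAModel, X: FeatureValueMatrix) -> np.ndarray:
    """Assign each sample to the class with minimal discriminant distance.

    Exact ties go to GP (the first class), a documented convention.
    """
    scores = dlda_scores(model, X)
    # argmin returns the first index on ties; classes[0] == "GP"
    best = np.argmin(scores, axis=0)
    return np.array([model.classes[i] for i in best], dtype=object)


class TrainedClassifier:
    """Fitted state plus the frozen training feature ids."""

    def __init__(self, kind: str, feature_ids: tuple, predict_fn):
        self.kind = kind
        self.feature_ids = tuple(feature_ids)
        self._predict_fn = predict_fn

    def predict(self, X: FeatureValueMatrix) -> np.ndarray:
        if X.feature_ids != self.feature_ids:
            raise ValueError(
                "feature ids of test matrix do not match training feature ids"
            )
        return np.asarray(self._predict_fn(X), dtype=object)


class _DLDATrainer:
    kind = "dlda"

    def train(self, X: FeatureValueMatrix, y) -> TrainedClassifier:
        model = train_dlda(X, y)
        return TrainedClassifier("dlda", X.feature_ids, lambda Xt: predict_dlda(model, Xt))


class _SklearnTrainer:
    def __init__(self, kind: str, seed=None, params=None):
        self.kind = kind
        self.seed = seed
        self.params = dict(params or {})

    def _make_estimator(self):
        if self.kind == "rf":
            opts = {"n_estimators": 500, "random_state": self.seed}
            opts.update(self.params)
            return RandomForestClassifier(**opts)
        opts = {"kernel": "linear", "C": 1.0, "random_state": self.seed}
        opts.update(self.params)
        return SVC(**opts)

    def train(self, X: FeatureValueMatrix, y) -> TrainedClassifier:
        est = self._make_estimator()
        est.fit(X.values.T, np.asarray(y, dtype=object))
        return TrainedClassifier(self.kind, X.feature_ids, lambda Xt: est.predict(Xt.values.T))


def classifier_adapter(kind: str, hyperparams=None, seed=None) -> _SklearnTrainer:
    """Adapter for the wrapped decision-forest / maximum-margin learners."""
    if kind not in ("rf", "svm"):
        raise ValueError(f"unknown adapter kind {kind!r}; expected 'rf' or 'svm'")
    return _SklearnTrainer(kind, seed=seed, params=hyperparams)


def make_trainer(kind: str, seed=None, params=None):
    """Factory for any of the three classifier kinds."""
    if kind == "dlda":
        return _DLDATrainer()
    if kind in ("rf", "svm"):
        return classifier_adapter(kind, hyperparams=params, seed=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
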