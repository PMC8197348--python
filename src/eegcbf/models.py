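"""The five binary CBF-recovery classifiers behind one train/score contract.

Hyperparameters are pinned to the published configuration:

LR    binomial generalized linear model (logistic regression, no penalty)
SVM   polynomial kernel of degree 3, box constraint C = 1, automatic kernel
      scale (gamma = 1 / (d * var) after z-scoring); Platt-calibrated scores
KNN   k = 9, Euclidean distance, squared-inverse distance weights
      (with a 1e-12 floor on zero distances)
RF    random-subspace ensemble of 30 decision trees, each grown on a random
      feature subset of size ceil(sqrt(d))
MLP   one hidden layer of 10 units ("10 hidden layers" read as the era's
      single-hidden-layer convention), deterministic full-batch quasi-Newton
      training (L-BFGS) standing in for scaled-conjugate-gradient

Every model is wrapped with train-set z-scoring and exposes a continuous
class-1 score in [0, 1]; the default decision threshold is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["CLASSIFIER_KINDS", "ClassifierSpec", "TrainedModel", "train", "predict_scores"]

CLASSIFIER_KINDS = ("LR", "SVM", "KNN", "RF", "MLP")

_DISTANCE_EPS = 1e-12


def _squared_inverse(distances: np.ndarray) -> np.ndarray:
    return 1.0 / (np.square(distances) + _DISTANCE_EPS)


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def _make_estimator(spec: ClassifierSpec, n_features: int):
    p = spec.params
    if spec.kind == "LR":
        # unpenalized binomial GLM
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if spec.kind == "SVM":
        svc = SVC(
            kernel="poly",
            degree=p.get("degree", 3),
            C=p.get("C", 1.0),
            gamma="scale",
            coef0=1.0,
        )
        # Platt-style sigmoid mapping of margins to [0, 1] via internal
        # (unshuffled, hence deterministic) stratified 5-fold predictions
        return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    if spec.kind == "KNN":
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 9),
            metric="euclidean",
            weights=_squared_inverse,
        )
    if spec.kind == "RF":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=p.get("n_estimators", 30),
            bootstrap=False,
            bootstrap_features=False,
            max_features=min(n_features, ceil(sqrt(n_features))),
            random_state=spec.seed,
        )
    if spec.kind == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=(p.get("hidden_units", 10),),
            solver="lbfgs",
            max_iter=2000,
            random_state=spec.seed,
        )
    raise AssertionError(spec.kind)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    pipeline: Pipeline
    n_features: int
    classes_: np.ndarray


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit one classifier (with internal train-set z-scoring)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", _make_estimator(spec, X.shape[1])),
        ]
    )
    pipe.fit(X, y)
    return TrainedModel(spec, pipe, X.shape[1], pipe.named_steps["clf"].classes_)


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 scores in [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    proba = model.pipeline.predict_proba(X)
    col = int(np.flatnonzero(model.classes_ == 1)[0]) if 1 in model.classes_ else 1
    return proba[:, col]
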