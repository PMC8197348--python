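"""Leave-one-animal-out evaluation, confusion metrics and ROC/AUC.

Each fold trains on seven of the eight animals (with SMOTE applied to the
training data only) and scores every sub-epoch of the held-out animal.
Because most animals contribute predominantly one class, per-fold
sensitivity/specificity are often undefined; predictions are therefore
pooled across folds before the confusion matrix, the metrics and the ROC
curve are computed. Class 1 (high CBF recovery) is "positive".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balancing import SmoteConfig, smote_augment
from .features import FEATURE_NAMES
from .models import CLASSIFIER_KINDS, ClassifierSpec, predict_scores, train
from .selection import run_selection

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "FoldPlan",
    "EvaluationReport",
    "make_loao_folds",
    "confusion",
    "metrics",
    "f1_score",
    "roc_auc",
    "evaluate_all",
    "load_published_performance_table",
]


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall <= 0:
        raise ValueError("F1 undefined when precision + recall is zero")
    return 2.0 * precision * recall / (precision + recall)


def load_published_performance_table() -> pd.DataFrame:
    """Published per-model operating points (accuracy, sensitivity,
    specificity, precision, F1, AUC), packaged for arithmetic-consistency
    checks of the metric definitions."""
    from importlib import resources

    with resources.files("eegcbf.data").joinpath(
        "published_model_performance.csv"
    ).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float = float("nan")
    roc: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class FoldPlan:
    """One fold per animal: (training animal ids, held-out animal id)."""

    folds: list[tuple[tuple[str, ...], str]]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_loao_folds(table: pd.DataFrame) -> FoldPlan:
    """Leave-one-animal-out fold plan over a labeled feature table."""
    animals = list(dict.fromkeys(table["animal_id"]))
    if len(animals) < 2:
        raise ValueError("leave-one-animal-out needs at least two animals")
    folds = []
    for held_out in animals:
        train_ids = tuple(a for a in animals if a != held_out)
        y_train = table.loc[table["animal_id"] != held_out, "group"]
        if y_train.nunique() < 2:
            raise ValueError(
                f"training set with animal {held_out!r} held out contains a "
                "single class"
            )
        folds.append((train_ids, held_out))
    return FoldPlan(folds)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Counts of TP/TN/FP/FN with class 1 as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from no predictions")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp, tn, fp, fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    Undefined ratios (zero denominator) are reported as NaN with a warning,
    never silently as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    if precision + sensitivity > 0:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    else:
        warnings.warn("F1 undefined; reported as NaN")
        f1 = float("nan")
    return MetricSet(accuracy, sensitivity, specificity, precision, f1)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points swept over all score thresholds and the trapezoidal AUC.

    Thresholds are the sorted unique scores plus ±inf endpoints; the AUC
    equals the normalized Mann–Whitney U statistic of the scores.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores lengths differ")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    points = []
    for thr in thresholds:
        pred = scores >= thr
        tpr = np.sum(pred & (y_true == 1)) / n_pos
        fpr = np.sum(pred & (y_true == 0)) / n_neg
        points.append((float(fpr), float(tpr)))
    fpr_arr = np.array([p[0] for p in points])
    tpr_arr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return points, auc


@dataclass
class EvaluationReport:
    per_model: dict[str, MetricSet]
    confusions: dict[str, ConfusionMatrix]
    mean_metrics: MetricSet
    n_instances: int

    def to_frame(self) -> pd.DataFrame:
        """One row per model (plus the cross-model mean), Table-style layout."""
        rows = []
        for kind, m in self.per_model.items():
            rows.append(
                {
                    "model": kind,
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "precision": m.precision,
                    "f1": m.f1,
                    "auc": m.auc,
                }
            )
        mm = self.mean_metrics
        rows.append(
            {
                "model": "mean",
                "accuracy": mm.accuracy,
                "sensitivity": mm.sensitivity,
                "specificity": mm.specificity,
                "precision": mm.precision,
                "f1": mm.f1,
                "auc": mm.auc,
            }
        )
        return pd.DataFrame(rows)


def evaluate_all(
    table: pd.DataFrame,
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
    smote: SmoteConfig | None = None,
    feature_names: list[str] | tuple[str, ...] | None = None,
    selection_in_fold: bool = False,
    selection_k: int = 10,
) -> EvaluationReport:
    """Pooled leave-one-animal-out evaluation of all classifiers.

    ``feature_names`` restricts the input features (e.g. the 10 selected
    parameters); with ``selection_in_fold`` the NCA + t-test selection is
    instead recomputed inside each training fold to avoid leakage.
    """
    if specs is None:
        specs = [ClassifierSpec(kind, seed=seed) for kind in CLASSIFIER_KINDS]
    smote_cfg = smote or SmoteConfig(seed=seed)
    features = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    plan = make_loao_folds(table)

    per_model: dict[str, MetricSet] = {}
    confusions: dict[str, ConfusionMatrix] = {}
    for spec in specs:
        y_all: list[np.ndarray] = []
        s_all: list[np.ndarray] = []
        for fold_i, (train_ids, held_out) in enumerate(plan.folds):
            tr = table[table["animal_id"] != held_out]
            te = table[table["animal_id"] == held_out]
            fold_features = features
            if selection_in_fold:
                fold_features = run_selection(tr, features, k=selection_k).selected
            X_tr = tr[fold_features].to_numpy(float)
            y_tr = tr["group"].to_numpy(int)
            X_te = te[fold_features].to_numpy(float)
            fold_smote = SmoteConfig(
                k_neighbors=smote_cfg.k_neighbors,
                seed=(smote_cfg.seed * 1000 + fold_i) % (2**31),
            )
            X_bal, y_bal, _ = smote_augment(X_tr, y_tr, fold_smote)
            model = train(spec, X_bal, y_bal)
            y_all.append(te["group"].to_numpy(int))
            s_all.append(predict_scores(model, X_te))
        y_true = np.concatenate(y_all)
        scores = np.concatenate(s_all)
        cm = confusion(y_true, (scores >= 0.5).astype(int))
        m = metrics(cm)
        m.roc, m.auc = roc_auc(y_true, scores)
        per_model[spec.kind] = m
        confusions[spec.kind] = cm

    mean_metrics = MetricSet(
        *(
            float(np.mean([getattr(m, f) for m in per_model.values()]))
            for f in ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")
        )
    )
    return EvaluationReport(per_model, confusions, mean_metrics, int(len(table)))
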