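"""Model assessment: regression metrics, confusion matrices, CV reports.

Regression models are scored by the coefficient of determination

    R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2,

the root mean square error and the mean absolute error.  The classifier is
scored by overall accuracy (percent correct) plus per-strain precision,
recall and F1 derived from the 3x3 confusion matrix (rows = true class,
columns = predicted class):

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall),

all expressed in percent.  Cross-validation reports carry the per-fold
metrics, their unweighted mean (the quoted CV figure) and the metrics of a
model refit on the full training partition and scored on the held-out test
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    mean_absolute_error,
    r2_score,
    root_mean_squared_error,
)

__all__ = [
    "RegressionMetrics",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "regression_metrics",
    "confusion",
    "classification_metrics",
    "f1_from_precision_recall",
    "crossval_report",
]


@dataclass(frozen=True)
class RegressionMetrics:
    """R^2 (unitless), RMSE and MAE (target units), sample count."""

    r2: float
    rmse: float
    mae: float
    n: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae, "n": self.n}


@dataclass
class ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def true_positives(self) -> np.ndarray:
        return np.diag(self.counts)

    def false_positives(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.true_positives()

    def false_negatives(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.true_positives()

    def row_normalized_pct(self) -> np.ndarray:
        """Percent-of-true-class view used for confusion-matrix displays."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_sums > 0, 100.0 * self.counts / row_sums, np.nan)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "counts": self.counts.tolist()}


@dataclass(frozen=True)
class ClassificationMetrics:
    """Per-class precision/recall/F1 and overall accuracy, all in percent."""

    precision_pct: dict
    recall_pct: dict
    f1_pct: dict
    accuracy_pct: float
    n: int

    def to_dict(self) -> dict:
        return {
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
            "f1_pct": self.f1_pct,
            "accuracy_pct": self.accuracy_pct,
            "n": self.n,
        }


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionMetrics:
    """R^2, RMSE and MAE of a prediction vector.

    With zero variance in ``y_true`` the R^2 denominator vanishes; the value
    is reported as NaN with a warning rather than raising.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    n = y_true.shape[0]
    if n < 2:
        raise ValueError("at least two observations are required")
    rmse = float(root_mean_squared_error(y_true, y_pred))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.allclose(y_true, y_true[0]):
        warnings.warn("y_true has zero variance; R^2 is undefined", RuntimeWarning, stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(r2_score(y_true, y_pred))
    return RegressionMetrics(r2=r2, rmse=rmse, mae=mae, n=n)


def confusion(y_true: Sequence, y_pred: Sequence, labels: Sequence) -> ConfusionMatrix:
    """Confusion counts over a fixed label order."""
    labels = list(labels)
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(arr) - set(labels)
        if bad:
            raise ValueError(f"{name} contains labels outside the class set: {sorted(map(str, bad))}")
    counts = _sk_confusion(list(y_true), list(y_pred), labels=labels)
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, in percent."""
    if precision_pct + recall_pct == 0:
        return float("nan")
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Per-class precision/recall/F1 (percent) and overall accuracy.

    A class never predicted (TP+FP = 0) or never present (TP+FN = 0) has the
    affected metric reported as NaN.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    tp = cm.true_positives().astype(float)
    fp = cm.false_positives().astype(float)
    fn = cm.false_negatives().astype(float)
    precision, recall, f1 = {}, {}, {}
    for i, label in enumerate(cm.labels):
        p = 100.0 * tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else float("nan")
        r = 100.0 * tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else float("nan")
        if np.isnan(p) or np.isnan(r) or p + r == 0:
            f = float("nan")
        else:
            f = f1_from_precision_recall(p, r)
        key = str(label)
        precision[key], recall[key], f1[key] = p, r, f
    accuracy = 100.0 * float(np.trace(cm.counts)) / cm.total
    return ClassificationMetrics(
        precision_pct=precision, recall_pct=recall, f1_pct=f1, accuracy_pct=accuracy, n=cm.total
    )


def _score(task: str, model, X, y, labels=None) -> dict:
    if task == "regression":
        return regression_metrics(y, model.predict(X)).to_dict()
    cm = confusion(y, model.predict(X), labels=labels)
    out = classification_metrics(cm).to_dict()
    out["confusion"] = cm.to_dict()
    return out


def crossval_report(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    plan,
    *,
    task: str = "regression",
    labels: Sequence | None = None,
) -> dict:
    """Fivefold CV on the training partition plus held-out test metrics.

    ``model_factory`` must return an unfitted estimator (typically a
    Pipeline of scaler + network); it is cloned per fold so standardization
    is refit on each fold's training rows.  The CV aggregate is the
    unweighted mean of fold metrics; the test row comes from a model refit
    on the full training partition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task == "classification" and labels is None:
        labels = sorted(np.unique(y).tolist())

    pos_of = {int(rid): k for k, rid in enumerate(range(X.shape[0]))}

    def rows(ids):
        idx = np.asarray([pos_of[int(i)] for i in ids], dtype=int)
        return X[idx], y[idx]

    fold_metrics = []
    for fold in range(plan.n_folds):
        fold_ids = plan.fold_ids(fold)
        if len(fold_ids) == 0:
            raise ValueError(f"fold {fold} is empty")
        train_ids = np.setdiff1d(plan.train_ids, fold_ids)
        model = clone(model_factory())
        model.fit(*rows(train_ids))
        Xf, yf = rows(fold_ids)
        fold_metrics.append(_score(task, model, Xf, yf, labels))

    scalar_keys = (
        ("r2", "rmse", "mae") if task == "regression" else ("accuracy_pct",)
    )
    cv_mean = {k: float(np.mean([m[k] for m in fold_metrics])) for k in scalar_keys}

    final = clone(model_factory())
    final.fit(*rows(plan.train_ids))
    test_metrics = _score(task, final, *rows(plan.test_ids), labels)
    if task == "classification":
        # CV confusion: pooled counts over the five fold evaluations
        pooled = np.sum([np.asarray(m["confusion"]["counts"]) for m in fold_metrics], axis=0)
        cv_confusion = ConfusionMatrix(pooled, tuple(labels)).to_dict()
    else:
        cv_confusion = None

    report = {
        "task": task,
        "folds": fold_metrics,
        "cv_mean": cv_mean,
        "test": test_metrics,
        "n_train": int(len(plan.train_ids)),
        "n_test": int(len(plan.test_ids)),
    }
    if cv_confusion is not None:
        report["cv_confusion"] = cv_confusion
    return report, final
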