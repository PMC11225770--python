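"""Classifier bank, evaluation metrics and validation protocol.

Seven classifiers behind one fit/predict contract (SVM, logistic
regression, decision tree, Manhattan-distance KNN, random forest,
gradient-boosted trees, Gaussian naive Bayes), confusion-count metrics
on the 0-100 scale, and the stratified 80/20 holdout and 5-fold
cross-validation protocol. "Pest present" (label 1) is the positive
class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

CLASSIFIER_KINDS = (
    "svm",
    "logistic_regression",
    "decision_tree",
    "knn",
    "random_forest",
    "xgb",
    "naive_bayes",
)


@dataclass
class ClassifierSpec:
    """Which learner to build, with optional hyperparameter overrides."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )


def make_classifier(spec: ClassifierSpec):
    """Instantiate the wrapped learner for a spec.

    KNN uses the Manhattan metric; seeded learners get the spec's seed.
    Unknown hyperparameter names are rejected by the constructors.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        return SVC(random_state=spec.seed, **hp)
    if spec.kind == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.kind == "knn":
        hp.setdefault("metric", "manhattan")
        return KNeighborsClassifier(**hp)
    if spec.kind == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.kind == "xgb":
        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=spec.seed, **hp)
    return GaussianNB(**hp)


def fit_predict(spec: ClassifierSpec, X_train, y_train, X_test) -> np.ndarray:
    """Fit the spec's learner and predict 0/1 labels for X_test."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    model = make_classifier(spec)
    model.fit(np.asarray(X_train), y_train)
    return np.asarray(model.predict(np.asarray(X_test)))


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN totals with label 1 ("pest") as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Accuracy, precision, recall and F1 on the 0-100 scale."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """A = (TP+TN)/(FP+TP+FN+TN) * 100, P = TP/(TP+FP) * 100,
    R = TP/(TP+FN) * 100, F1 = 2 P R / (P + R)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on an empty evaluation")
    accuracy = 100.0 * (counts.TP + counts.TN) / counts.total
    precision = 100.0 * _safe_ratio(counts.TP, counts.TP + counts.FP, "precision")
    recall = 100.0 * _safe_ratio(counts.TP, counts.TP + counts.FN, "recall")
    f1 = 2.0 * _safe_ratio(recall * precision, recall + precision, "f1")
    return MetricsReport(accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1)


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    return compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred))


def holdout_split(X, y, test_fraction: float = 0.2, seed: int = 0):
    """Stratified train/test index split (80/20 by default).

    Returns ``(train_idx, test_idx)`` — disjoint, exhaustive, seeded.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to stratify")
    idx = np.arange(y.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def cross_validate(spec: ClassifierSpec, X, y, folds: int = 5, seed: int = 0):
    """Stratified k-fold evaluation.

    Returns ``(per_fold, mean_report)`` — a list of per-fold
    :class:`MetricsReport` and their unweighted mean.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if folds > y.size:
        raise ValueError("folds must not exceed the number of samples")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in splitter.split(X, y):
        y_pred = fit_predict(spec, X[train_idx], y[train_idx], X[test_idx])
        per_fold.append(evaluate_predictions(y[test_idx], y_pred))
    mean = MetricsReport(
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        precision=float(np.mean([m.precision for m in per_fold])),
        recall=float(np.mean([m.recall for m in per_fold])),
        f1=float(np.mean([m.f1 for m in per_fold])),
    )
    return per_fold, mean


def metrics_table(rows: dict) -> pd.DataFrame:
    """Rows = classifier name -> MetricsReport; columns A/P/R/F1."""
    return pd.DataFrame(
        {name: report.to_dict() for name, report in rows.items()}
    ).T[["accuracy", "precision", "recall", "f1"]]
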