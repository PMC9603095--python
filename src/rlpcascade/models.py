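"""Member classifiers: training, 10-fold cross-validation, the metric
suite, and per-training-set champion selection.

Metrics are computed from pooled out-of-fold confusion matrices.  For
multiclass problems each class is scored one-vs-rest and the suite is
macro-averaged (configurable to micro).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .dataset_builder import TrainingSet, assign_folds, smote


class ModelError(ValueError):
    pass


#: Fixed algorithm order: the registry order is also the champion tie-break.
ALGORITHM_ORDER = (
    "adaboost",
    "calibrated",
    "gradient_boosting",
    "knn",
    "lda",
    "qda",
    "logistic_cv",
    "mlp",
)


def make_estimator(algorithm_id: str, seed: Optional[int] = 0):
    """Instantiate a registry algorithm with library-default hyperparameters
    (stochastic ones seeded)."""
    if algorithm_id == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if algorithm_id == "calibrated":
        return CalibratedClassifierCV(LinearSVC(random_state=seed), cv=3)
    if algorithm_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if algorithm_id == "knn":
        return KNeighborsClassifier()
    if algorithm_id == "lda":
        return LinearDiscriminantAnalysis()
    if algorithm_id == "qda":
        return QuadraticDiscriminantAnalysis()
    if algorithm_id == "logistic_cv":
        return LogisticRegressionCV(max_iter=1000, random_state=seed)
    if algorithm_id == "mlp":
        # "deep neural network": small feed-forward net; width is config
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=500, random_state=seed)
    raise ModelError(f"unknown algorithm {algorithm_id!r}")


@dataclass
class MemberModel:
    """One fitted member classifier plus its provenance and CV metrics."""

    algorithm_id: str
    feature_type: str
    dataset_id: str
    stage: str
    estimator: object
    classes: list[str]
    metrics: Optional[dict] = None
    seed: int = 0

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))

    def predict_proba(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        return np.asarray(proba)

    def manifest(self) -> dict:
        return {
            "algorithm": self.algorithm_id,
            "feature_type": self.feature_type,
            "dataset_id": self.dataset_id,
            "stage": self.stage,
            "classes": list(self.classes),
            "seed": int(self.seed),
            "metrics": self.metrics,
            "hyperparameters": {
                k: repr(v) for k, v in self.estimator.get_params(deep=False).items()
            },
        }


@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest counts derived from prediction/label pairs."""

    classes: list
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.tp, self.fp, self.tn, self.fn):
            if np.any(np.asarray(arr) < 0):
                raise ModelError("negative confusion-matrix counts")

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])

    @classmethod
    def binary(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionMatrix":
        """Two-class matrix from the positive class's scalar counts."""
        return cls(
            classes=["positive", "negative"],
            tp=np.array([tp, tn]),
            fp=np.array([fp, fn]),
            tn=np.array([tn, tp]),
            fn=np.array([fn, fp]),
        )

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, classes=None, positive=None
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = list(classes)
        if positive is not None and positive in classes:
            classes = [positive] + [c for c in classes if c != positive]
        tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes])
        fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes])
        fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes])
        tn = np.array([np.sum((y_true != c) & (y_pred != c)) for c in classes])
        return cls(classes=classes, tp=tp, fp=fp, tn=tn, fn=fn)


METRIC_NAMES = ("ACC", "F1", "FDR", "MCC", "Precision", "Sensitivity", "Specificity")


def _safe_div(num: float, den: float, metric: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {metric}; reporting 0")
        return 0.0
    return num / den


def _binary_metrics(tp: float, fp: float, tn: float, fn: float) -> dict:
    total = tp + fp + tn + fn
    acc = _safe_div(tp + tn, total, "ACC")
    precision = _safe_div(tp, tp + fp, "Precision")
    sensitivity = _safe_div(tp, tp + fn, "Sensitivity")
    specificity = _safe_div(tn, tn + fp, "Specificity")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, "F1")
    fdr = _safe_div(fp, fp + tp, "FDR")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    return {
        "ACC": acc,
        "F1": f1,
        "FDR": fdr,
        "MCC": mcc,
        "Precision": precision,
        "Sensitivity": sensitivity,
        "Specificity": specificity,
    }


def compute_metrics(cm: ConfusionMatrix, average: str = "macro") -> dict:
    """Metric suite {ACC, F1, FDR, MCC, Precision, Sensitivity, Specificity}.

    Binary problems use the first class alphabetically as "positive" only
    for bookkeeping — with two classes the one-vs-rest suites are averaged
    just like multiclass, which for ACC/MCC coincides with the binary
    definitions.  Zero denominators yield 0 with a warning.
    """
    if cm.total == 0:
        raise ModelError("empty confusion matrix")
    if average not in ("macro", "micro"):
        raise ModelError(f"unknown averaging mode {average!r}")
    if len(cm.classes) == 2:
        # report the positive-class (first-class) suite directly
        return _binary_metrics(cm.tp[0], cm.fp[0], cm.tn[0], cm.fn[0])
    if average == "micro":
        return _binary_metrics(cm.tp.sum(), cm.fp.sum(), cm.tn.sum(), cm.fn.sum())
    suites = [
        _binary_metrics(cm.tp[i], cm.fp[i], cm.tn[i], cm.fn[i])
        for i in range(len(cm.classes))
    ]
    return {name: float(np.mean([s[name] for s in suites])) for name in METRIC_NAMES}


def _check_training_set(ts: TrainingSet) -> None:
    counts = ts.y.value_counts()
    if len(counts) < 2:
        raise ModelError(f"training set {ts.dataset_id} has fewer than 2 classes")
    if counts.min() < 2:
        raise ModelError(
            f"training set {ts.dataset_id} has a class with fewer than 2 rows"
        )


def train_member(
    training_set: TrainingSet,
    algorithm_id: str,
    seed: int = 0,
    balance: bool = True,
    metrics: Optional[dict] = None,
) -> MemberModel:
    """Fit one member on a full training set (SMOTE-balanced by default)."""
    _check_training_set(training_set)
    X = np.asarray(training_set.X, dtype=float)
    y = np.asarray(training_set.y)
    if balance and len(set(training_set.y.value_counts())) > 1:
        X, y = smote(X, y, seed=seed)
    est = make_estimator(algorithm_id, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return MemberModel(
        algorithm_id=algorithm_id,
        feature_type=training_set.feature_type,
        dataset_id=training_set.dataset_id,
        stage=training_set.stage,
        estimator=est,
        classes=[str(c) for c in est.classes_],
        metrics=metrics,
        seed=seed,
    )


def cross_validate(
    training_set: TrainingSet,
    algorithm_id: str,
    n_folds: int = 10,
    seed: int = 0,
    balance: bool = True,
    average: str = "macro",
) -> dict:
    """K-fold cross-validation with a pooled out-of-fold confusion matrix.

    Class balancing (SMOTE) is applied to the training folds only — never
    to a validation fold — so synthetic interpolants cannot leak into the
    evaluation.
    """
    _check_training_set(training_set)
    X = np.asarray(training_set.X, dtype=float)
    y = np.asarray(training_set.y)
    folds = assign_folds(y, n_folds=n_folds, seed=seed)
    y_pred = np.empty_like(y)
    for f in np.unique(folds):
        train_mask = folds != f
        X_tr, y_tr = X[train_mask], y[train_mask]
        if balance and len(set(np.unique(y_tr, return_counts=True)[1])) > 1:
            X_tr, y_tr = smote(X_tr, y_tr, seed=seed + int(f))
        est = make_estimator(algorithm_id, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X_tr, y_tr)
        y_pred[~train_mask] = est.predict(X[~train_mask])
    positive = "RLP" if "RLP" in set(y) else None
    cm = ConfusionMatrix.from_predictions(
        y, y_pred, classes=sorted(set(y)), positive=positive
    )
    record = compute_metrics(cm, average=average)
    record["Data Set"] = training_set.dataset_id
    record["Algorithm"] = algorithm_id
    return record


def select_champion(metric_records: Sequence[dict]) -> dict:
    """Champion = best MCC; ties break by ACC, then by fixed registry order."""
    if not metric_records:
        raise ModelError("no candidate metric records")

    def sort_key(rec: dict):
        try:
            order = ALGORITHM_ORDER.index(rec["Algorithm"])
        except ValueError:
            order = len(ALGORITHM_ORDER)
        return (-rec["MCC"], -rec["ACC"], order)

    return min(metric_records, key=sort_key)


def metrics_table(records: Sequence[dict]) -> pd.DataFrame:
    """Per-set metrics in the standard report layout."""
    columns = ["Data Set", "Algorithm", *METRIC_NAMES]
    return pd.DataFrame([{c: r[c] for c in columns} for r in records])
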