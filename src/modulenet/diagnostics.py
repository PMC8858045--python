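"""Diagnostic panel classification.

A small gene panel (typically the key genes from the network analysis) is
used as features for a linear support-vector machine. Features are
standardised with training-set statistics stored in the model, so held-out
samples are transformed consistently. Evaluation pools out-of-fold
predictions from stratified k-fold cross-validation into one confusion
matrix and one ROC curve, matching how whole-cohort counts are usually
reported for small clinical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionMatrix

__all__ = [
    "ConfusionMetrics",
    "RocResult",
    "PanelModel",
    "train_panel_svm",
    "cross_validate",
    "evaluate",
]


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class RocResult:
    """ROC points (fpr, tpr) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @classmethod
    def from_scores(cls, scores, labels) -> "RocResult":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        fpr, tpr, _ = roc_curve(labels, scores)
        return cls(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


@dataclass
class PanelModel:
    panel: list[str]
    pipeline: Pipeline
    kernel: str
    c: float
    seed: int

    def metadata(self) -> dict:
        scaler: StandardScaler = self.pipeline.named_steps["scale"]
        return {
            "panel": list(self.panel),
            "kernel": self.kernel,
            "C": self.c,
            "seed": self.seed,
            "feature_means": scaler.mean_.tolist(),
            "feature_sds": scaler.scale_.tolist(),
        }


def _panel_features(expr: ExpressionMatrix, panel) -> np.ndarray:
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in panel if g not in idx]
    if missing:
        raise ValueError(f"panel genes absent from expression matrix: {missing}")
    return expr.values[[idx[g] for g in panel]].T  # samples x panel


def _labels(expr: ExpressionMatrix) -> np.ndarray:
    return expr.case_mask.astype(int)


def train_panel_svm(
    expr: ExpressionMatrix,
    panel,
    kernel: str = "linear",
    c: float = 1.0,
    seed: int = 0,
) -> PanelModel:
    """Fit the standardise-then-SVM pipeline on the panel features."""
    x = _panel_features(expr, panel)
    y = _labels(expr)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=c, random_state=seed)),
        ]
    )
    pipe.fit(x, y)
    return PanelModel(panel=list(panel), pipeline=pipe, kernel=kernel, c=c, seed=seed)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMetrics:
    return ConfusionMetrics(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
    )


def cross_validate(
    expr: ExpressionMatrix,
    panel,
    k: int = 10,
    kernel: str = "linear",
    c: float = 1.0,
    seed: int = 0,
) -> tuple[ConfusionMetrics, RocResult]:
    """Stratified k-fold CV; out-of-fold predictions pooled.

    If ``k`` exceeds the smallest class size the fold count degrades to
    that size with a warning. Decision-function scores (not probabilities)
    feed the pooled ROC.
    """
    import warnings

    if k < 2:
        raise ValueError("k must be >= 2")
    x = _panel_features(expr, panel)
    y = _labels(expr)
    smallest = int(min(y.sum(), len(y) - y.sum()))
    if smallest < 2:
        raise ValueError("need at least 2 samples per class")
    if k > smallest:
        warnings.warn(f"k={k} exceeds smallest class size; using k={smallest}")
        k = smallest
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(x, y):
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel=kernel, C=c, random_state=seed)),
            ]
        )
        pipe.fit(x[train_idx], y[train_idx])
        pred[test_idx] = pipe.predict(x[test_idx])
        scores[test_idx] = pipe.decision_function(x[test_idx])
    return _confusion(y, pred), RocResult.from_scores(scores, y)


def evaluate(
    model: PanelModel, expr: ExpressionMatrix
) -> tuple[ConfusionMetrics, RocResult]:
    """Apply a trained model (with its stored standardisation) to new data."""
    x = _panel_features(expr, model.panel)
    y = _labels(expr)
    pred = model.pipeline.predict(x)
    scores = model.pipeline.decision_function(x)
    cm = _confusion(y, pred)
    roc = (
        RocResult.from_scores(scores, y)
        if 0 < y.sum() < len(y)
        else RocResult(fpr=np.array([]), tpr=np.array([]), auc=float("nan"))
    )
    return cm, roc
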