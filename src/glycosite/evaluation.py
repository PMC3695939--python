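"""Threshold-dependent metrics, ROC/AUC, and k-fold cross-validation.

Sensitivity, specificity and accuracy are reported as percentages; MCC lies
in [-1, 1] with the convention that a zero denominator yields 0. ROC curves
are threshold-independent and the AUC equals the Mann-Whitney concordance
probability (ties handled by the midrank convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from glycosite.patterns import Pattern


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Per-threshold performance summary; AUC is threshold-independent."""

    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    mcc: float
    auc: float | None = None


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts for binary labels (1 = glycosylated)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """Sn, Sp, Acc (percent) and MCC from a confusion matrix.

    Sn = 100*TP/(TP+FN); Sp = 100*TN/(TN+FP); Acc = 100*(TP+TN)/total;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    when any factor of the denominator vanishes.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero instances")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    specificity = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    accuracy = 100.0 * (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return Metrics(sensitivity, specificity, accuracy, mcc)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR per distinct threshold, descending) and trapezoid AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass(frozen=True)
class CrossValidationResult:
    fold_metrics: tuple[Metrics, ...]
    mean: Metrics
    sd: Metrics
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, test) indices

    def to_table(self):
        """Fold-by-fold report with a final mean +/- SD row, as a DataFrame."""
        import pandas as pd

        rows = [
            {
                "fold": i + 1,
                "Sn": m.sensitivity,
                "Sp": m.specificity,
                "Acc": m.accuracy,
                "MCC": m.mcc,
                "AUC": m.auc,
            }
            for i, m in enumerate(self.fold_metrics)
        ]
        rows.append(
            {
                "fold": "mean±sd",
                "Sn": f"{self.mean.sensitivity:.2f}±{self.sd.sensitivity:.2f}",
                "Sp": f"{self.mean.specificity:.2f}±{self.sd.specificity:.2f}",
                "Acc": f"{self.mean.accuracy:.2f}±{self.sd.accuracy:.2f}",
                "MCC": f"{self.mean.mcc:.3f}±{self.sd.mcc:.3f}",
                "AUC": f"{self.mean.auc:.3f}±{self.sd.auc:.3f}",
            }
        )
        return pd.DataFrame(rows)


def cross_validate(
    patterns: Sequence[Pattern] | None,
    encoder: Callable | None,
    config,
    k: int = 5,
    seed: int = 0,
    X=None,
    y=None,
    stratified: bool = True,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of one SVM configuration.

    Either ``patterns`` + ``encoder`` or pre-encoded ``X``/``y`` must be
    given. Each instance is tested exactly once; per-fold Sn/Sp/Acc/MCC are
    computed at ``config.threshold`` and AUC from the fold's decision scores.
    The summary reports the across-fold mean and sample (n-1) SD.
    ``stratified=False`` uses a plain shuffled partition instead (may fail on
    heavily imbalanced data when a fold loses a class).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    from glycosite.features import encode_dataset
    from glycosite.model import classify, decision_scores, train

    if X is None:
        if patterns is None or encoder is None:
            raise ValueError("provide patterns+encoder or X and y")
        X, y, _ = encode_dataset(patterns, encoder)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(y):
        raise ValueError(f"more folds ({k}) than instances ({len(y)})")
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    fold_metrics: list[Metrics] = []
    folds = []
    for train_idx, test_idx in splitter.split(X, y):
        if len(set(y[train_idx].tolist())) < 2:
            raise ValueError("a fold's training portion lost a class; use stratified=True")
        model = train(X[train_idx], y[train_idx], config)
        scores = decision_scores(model, X[test_idx])
        m = metrics_from_counts(confusion(y[test_idx], classify(scores, config.threshold)))
        _, auc = roc_auc(scores, y[test_idx])
        fold_metrics.append(
            Metrics(m.sensitivity, m.specificity, m.accuracy, m.mcc, auc)
        )
        folds.append((tuple(train_idx.tolist()), tuple(test_idx.tolist())))

    def _agg(fn) -> Metrics:
        return Metrics(
            fn([m.sensitivity for m in fold_metrics]),
            fn([m.specificity for m in fold_metrics]),
            fn([m.accuracy for m in fold_metrics]),
            fn([m.mcc for m in fold_metrics]),
            fn([m.auc for m in fold_metrics]),
        )

    mean = _agg(lambda v: float(np.mean(v)))
    sd = _agg(lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
    return CrossValidationResult(tuple(fold_metrics), mean, sd, tuple(folds))
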