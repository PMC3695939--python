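"""RBF-kernel SVM training, scoring, thresholding and grid search.

The classifier follows the SVM-light style of glycosite predictors: an RBF
kernel, a cost factor ``j`` multiplying the penalty of errors on the positive
(glycosylated) class to counter the heavy negative excess, and a decision
threshold ``t`` swept in [-1, 1] to trade sensitivity against specificity.

Grid search evaluates every (gamma, C, j) combination by stratified k-fold
cross-validation and selects the configuration with the best mean MCC at the
default threshold 0. To keep the 240-point default grid tractable, the
pairwise squared-distance matrix is computed once and each fold reuses a
precomputed kernel across all C/j values of a gamma — numerically identical
to refitting with the built-in RBF kernel.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from glycosite.evaluation import confusion, metrics_from_counts, roc_auc
from glycosite.features import FeatureVector

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Default hyperparameter grid: 6 gammas x 10 costs x 4 cost factors.
DEFAULT_GRID: dict[str, tuple] = {
    "gamma": (1.0, 0.1, 0.01, 0.001, 0.0001, 0.00001),
    "C": tuple(range(1, 11)),
    "j": (1.0, 2.0, 3.0, 4.0),
}


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one RBF-SVM model."""

    gamma: float
    C: float = 1.0
    j: float = 1.0  # cost factor: weight multiplier on the positive class
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.j < 1:
            raise ValueError(f"cost factor j must be >= 1, got {self.j}")
        if not -1 <= self.threshold <= 1:
            warnings.warn(
                f"threshold {self.threshold} outside [-1, 1]; RBF decision values "
                "are unbounded so this is allowed but unusual",
                stacklevel=2,
            )


@dataclass
class TrainedModel:
    """A fitted SVM plus the metadata needed to refuse incompatible inputs."""

    estimator: SVC
    schema: str
    config: TrainingConfig
    fingerprint: str
    version: int = MODEL_FORMAT_VERSION


def _as_matrix(X: Sequence[FeatureVector] | np.ndarray) -> tuple[np.ndarray, str | None]:
    if isinstance(X, np.ndarray):
        return X, None
    vectors = list(X)
    if vectors and isinstance(vectors[0], FeatureVector):
        schemas = {v.schema for v in vectors}
        if len(schemas) > 1:
            raise ValueError(f"inconsistent feature schemas {sorted(schemas)}")
        return np.vstack([v.values for v in vectors]), schemas.pop()
    return np.asarray(X, dtype=float), None


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(
    X: Sequence[FeatureVector] | np.ndarray,
    y: Sequence[int],
    config: TrainingConfig,
    schema: str | None = None,
) -> TrainedModel:
    """Fit an RBF-SVM with class weights {positive: j, negative: 1}.

    ``y`` uses 1 for glycosylated and 0 for non-glycosylated. The fit is
    deterministic for fixed inputs and configuration.
    """
    X, inferred = _as_matrix(X)
    schema = schema or inferred or f"raw{X.shape[1]}"
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training labels must contain both classes (0 and 1)")
    estimator = SVC(
        kernel="rbf",
        gamma=config.gamma,
        C=config.C,
        class_weight={1: config.j, 0: 1.0},
        cache_size=500,
    )
    estimator.fit(X, y)
    return TrainedModel(
        estimator=estimator,
        schema=schema,
        config=config,
        fingerprint=_fingerprint(X, y),
    )


def decision_scores(
    model: TrainedModel, X: Sequence[FeatureVector] | np.ndarray
) -> np.ndarray:
    """Real-valued decision output; larger means more glycosite-like."""
    X, schema = _as_matrix(X)
    if schema is not None and schema != model.schema:
        raise ValueError(
            f"feature schema {schema!r} does not match model schema {model.schema!r}"
        )
    expected = model.estimator.n_features_in_
    if X.shape[1] != expected:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({expected})"
        )
    return model.estimator.decision_function(X)


def classify(scores: Sequence[float], threshold: float = 0.0) -> np.ndarray:
    """Label 1 (glycosylated) iff score >= threshold."""
    if not -1 <= threshold <= 1:
        warnings.warn(f"threshold {threshold} outside the usual [-1, 1] range", stacklevel=2)
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def _fold_indices(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if k > len(y):
        raise ValueError(f"more folds ({k}) than samples ({len(y)})")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


def grid_search(
    X: Sequence[FeatureVector] | np.ndarray,
    y: Sequence[int],
    grid: Mapping[str, Sequence[float]] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[TrainingConfig, pd.DataFrame]:
    """Exhaustive (gamma, C, j) search by stratified k-fold cross-validation.

    Every grid point is scored by mean MCC at threshold 0; ties are broken by
    higher mean accuracy, then smaller C, then smaller gamma. Returns the
    winning configuration and the full cross-validation table for audit.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    grid = dict(grid or DEFAULT_GRID)
    gammas = list(grid.get("gamma", DEFAULT_GRID["gamma"]))
    Cs = list(grid.get("C", DEFAULT_GRID["C"]))
    js = list(grid.get("j", DEFAULT_GRID["j"]))
    if not (gammas and Cs and js):
        raise ValueError("grid must contain at least one gamma, C and j")
    folds = _fold_indices(y, k, seed)

    # All grid points share the folds; the squared-distance matrix is computed
    # once so each (fold, gamma) kernel is a single elementwise exp.
    sqdist = pairwise_distances(X, metric="sqeuclidean")

    rows = []
    for gamma in gammas:
        kernel = np.exp(-gamma * sqdist)
        per_point: dict[tuple[float, float], list] = {(C, j): [] for C in Cs for j in js}
        for train_idx, test_idx in folds:
            K_train = kernel[np.ix_(train_idx, train_idx)]
            K_test = kernel[np.ix_(test_idx, train_idx)]
            y_train, y_test = y[train_idx], y[test_idx]
            for C in Cs:
                for j in js:
                    svc = SVC(kernel="precomputed", C=C, class_weight={1: j, 0: 1.0})
                    svc.fit(K_train, y_train)
                    scores = svc.decision_function(K_test)
                    m = metrics_from_counts(confusion(y_test, classify(scores, 0.0)))
                    _, auc = roc_auc(scores, y_test)
                    per_point[(C, j)].append((m.mcc, m.accuracy, auc))
        for (C, j), fold_stats in per_point.items():
            arr = np.array(fold_stats)
            rows.append(
                {
                    "gamma": gamma,
                    "C": C,
                    "j": j,
                    "mean_mcc": arr[:, 0].mean(),
                    "sd_mcc": arr[:, 0].std(ddof=1) if len(arr) > 1 else 0.0,
                    "mean_accuracy": arr[:, 1].mean(),
                    "mean_auc": arr[:, 2].mean(),
                }
            )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_mcc", "mean_accuracy", "C", "gamma"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    best = ranked.iloc[0]
    best_config = TrainingConfig(gamma=float(best.gamma), C=float(best.C), j=float(best.j))
    logger.info("grid search best: %s (mean MCC %.3f)", best_config, best.mean_mcc)
    return best_config, table.reset_index(drop=True)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "version": model.version,
            "schema": model.schema,
            "config": model.config,
            "fingerprint": model.fingerprint,
            "estimator": model.estimator,
        },
        Path(path),
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(Path(path))
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('version')!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        estimator=payload["estimator"],
        schema=payload["schema"],
        config=payload["config"],
        fingerprint=payload["fingerprint"],
        version=payload["version"],
    )
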