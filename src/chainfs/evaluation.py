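"""Cross-validated classification accuracy — the wrapper's fitness oracle.

The reference protocol is stratified 10-fold cross-validation of an RBF
support-vector classifier whose penalty C and kernel width gamma are chosen
by grid search.  To avoid leakage, per-fold feature standardization and the
grid search both run on the training split only (the search uses an inner
3-fold loop).  The classifier is injectable so that the subset search can
use a much cheaper surrogate (nearest-centroid) where thousands of subset
evaluations are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import FeatureTable, check_labels

__all__ = [
    "EvaluatorConfig",
    "MetricsReport",
    "stratified_folds",
    "cv_accuracy",
    "make_evaluator",
    "report_metrics",
]

DEFAULT_PENALTY_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class EvaluatorConfig:
    """Settings for the accuracy oracle.

    ``classifier``: ``"svm-rbf"`` (grid-searched SVC, the reference
    protocol), ``"nearest-centroid"`` (fast surrogate for subset search),
    or a zero-argument factory returning any scikit-learn classifier.
    """

    folds: int = 10
    classifier: str | Callable[[], BaseEstimator] = "svm-rbf"
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 3
    repetitions: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def build(self, seed: int) -> BaseEstimator:
        """Instantiate the classification pipeline (standardize -> classify)."""
        if callable(self.classifier):
            clf: BaseEstimator = self.classifier()
        elif self.classifier == "nearest-centroid":
            clf = NearestCentroid()
        elif self.classifier == "svm-rbf":
            inner = StratifiedKFold(self.inner_folds, shuffle=True,
                                    random_state=seed)
            clf = GridSearchCV(
                SVC(kernel="rbf"),
                {"C": list(self.penalty_grid), "gamma": list(self.gamma_grid)},
                cv=inner, n_jobs=None)
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class MetricsReport:
    """Mean accuracy across runs, final subset length and reduction rate."""

    acc_mean: float
    acc_per_run: list[float]
    len: int
    drr: float


def stratified_folds(labels: np.ndarray, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..k-1 per sample) preserving class proportions.

    Every sample lands in exactly one test fold; within each class, fold
    sizes differ by at most one.  Deterministic for a fixed generator state.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, need >= {k}")
    seed = int(rng.integers(2**31))
    splitter = StratifiedKFold(k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(labels), 1)),
                                                        labels)):
        assignment[test_idx] = fold
    return assignment


def cv_accuracy(table: FeatureTable, labels: np.ndarray,
                config: EvaluatorConfig | None = None,
                rng: np.random.Generator | None = None) -> float:
    """Mean stratified k-fold test accuracy of the configured classifier.

    Standardization and (for the SVM) the hyperparameter grid search are
    fitted on each training split only; the test fold is touched exactly
    once, for scoring.
    """
    config = config or EvaluatorConfig()
    rng = rng or np.random.default_rng()
    labels = check_labels(labels, table.n_samples)
    if table.n_features < 1:
        raise ValueError("empty feature subset")
    folds = stratified_folds(labels, config.folds, rng)
    seed = int(rng.integers(2**31))
    X, y = table.values, np.asarray(labels)
    accs = []
    for fold in range(config.folds):
        test = folds == fold
        model = config.build(seed)
        model.fit(X[~test], y[~test])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def make_evaluator(table: FeatureTable, labels: np.ndarray,
                   config: EvaluatorConfig, seed: int) -> Callable[[np.ndarray], float]:
    """Bind (table, labels, config) into the ``mask -> accuracy`` callable
    that the subset search consumes.

    The CV split and classifier seed derive from ``seed`` alone, so two
    evaluations of the same mask return the same accuracy and evaluations
    are order-independent.
    """
    labels = check_labels(labels, table.n_samples)

    def evaluate(mask: np.ndarray) -> float:
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if len(idx) == 0:
            raise ValueError("empty mask")
        sub = FeatureTable(table.values[:, idx],
                           [table.feature_ids[i] for i in idx])
        return cv_accuracy(sub, labels, config, np.random.default_rng(seed))

    return evaluate


def report_metrics(acc_per_run: list[float], subset_len: int,
                   original_dim: int) -> MetricsReport:
    """Aggregate per-run accuracies with the dimension reduction rate.

    DRR = selected features / original features; smaller means a stronger
    reduction.
    """
    if len(acc_per_run) < 1:
        raise ValueError("need at least one run")
    if not 1 <= subset_len <= original_dim:
        raise ValueError("subset length out of range")
    return MetricsReport(
        acc_mean=float(np.mean(acc_per_run)),
        acc_per_run=[float(a) for a in acc_per_run],
        len=int(subset_len),
        drr=subset_len / original_dim,
    )
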