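"""Gaussian Naive Bayes with best-first wrapper feature selection and k-fold CV.

The classifier stores per-class priors and per-class, per-feature Gaussian
parameters (sample mean, biased sample variance floored for numerical
safety); posteriors are computed in log space.  Model selection wraps the
classifier in a forward best-first search scored by stratified
cross-validation accuracy, as used for the autonomy and diagnosis
classification tasks.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANCE_FLOOR",
    "AUTONOMY_FEATURES",
    "DIAGNOSIS_FEATURES",
    "LabeledFeatureTable",
    "GaussianNBModel",
    "CVReport",
    "SelectionResult",
    "fit_naive_bayes",
    "predict_class",
    "predict_table",
    "cross_validate",
    "select_features_best_first",
]

#: Relative variance floor (scaled by the squared global feature scale).
VARIANCE_FLOOR = 1e-9

#: Feature set used for the autonomy classification task.
AUTONOMY_FEATURES = (
    "single_task_total_duration",
    "single_task_gap_duration",
    "single_task_standard_deviation_steps",
    "dual_task_gap_duration",
    "dual_task_max_steps",
    "person_using_pharmacybasket_frequency_of_event",
    "person_using_pharmacybasket_duration_of_event",
)

#: Feature set used for the diagnosis classification task.
DIAGNOSIS_FEATURES = (
    "age",
    "single_task_average_steps",
    "single_task_speed_average_from_centroid_information",
    "dual_task_max_steps",
    "dual_task_min_steps",
    "person_reading_inchairreadingtable_duration_of_event",
)


@dataclass
class LabeledFeatureTable:
    """Numeric feature matrix with one class label per row.

    ``classes`` lists the distinct labels in order of first appearance; this
    order is the deterministic tie-break for predictions.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.feature_names = tuple(self.feature_names)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> tuple:
        seen: dict = {}
        for label in self.y:
            seen.setdefault(label, None)
        return tuple(seen)

    def select(self, features: Sequence[str]) -> "LabeledFeatureTable":
        idx = [self.feature_names.index(f) for f in features]
        return LabeledFeatureTable(self.X[:, idx], self.y, tuple(features))

    def subset_rows(self, rows: np.ndarray) -> "LabeledFeatureTable":
        return LabeledFeatureTable(self.X[rows], self.y[rows], self.feature_names)

    @classmethod
    def from_dataframe(cls, df, feature_names: Sequence[str],
                       label_col: str) -> "LabeledFeatureTable":
        X = df[list(feature_names)].to_numpy(dtype=float)
        return cls(X, df[label_col].to_numpy(dtype=object), tuple(feature_names))


@dataclass(frozen=True)
class GaussianNBModel:
    classes: tuple
    priors: np.ndarray          # (n_classes,)
    means: np.ndarray           # (n_classes, n_features)
    variances: np.ndarray       # (n_classes, n_features)
    feature_names: tuple


def fit_naive_bayes(table: LabeledFeatureTable,
                    variance_floor: float = VARIANCE_FLOOR) -> GaussianNBModel:
    """Fit class priors and per-class Gaussian parameters.

    Priors are empirical class frequencies; per-class variance uses the
    biased (denominator ``n``) estimator and is floored at
    ``variance_floor * scale**2`` where the scale is the global per-feature
    standard deviation, so constant features keep finite likelihoods.
    """
    if table.n == 0:
        raise ValueError("cannot fit on an empty table")
    classes = table.classes
    n, p = table.X.shape
    global_var = table.X.var(axis=0)
    floor = np.maximum(variance_floor * np.maximum(global_var, 1.0), 1e-300)

    priors = np.empty(len(classes))
    means = np.empty((len(classes), p))
    variances = np.empty((len(classes), p))
    for i, c in enumerate(classes):
        rows = table.X[table.y == c]
        priors[i] = len(rows) / n
        means[i] = rows.mean(axis=0)
        variances[i] = np.maximum(rows.var(axis=0), floor)
    return GaussianNBModel(classes, priors, means, variances, table.feature_names)


def _log_joint(model: GaussianNBModel, X: np.ndarray) -> np.ndarray:
    """Log prior + summed log Gaussian densities, shape (n_rows, n_classes)."""
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))
        feat = model.feature_names[bad[0][1]] if len(model.feature_names) else "?"
        raise ValueError(f"non-finite value in feature {feat!r}")
    diff = X[:, None, :] - model.means[None, :, :]       # (n, c, p)
    var = model.variances[None, :, :]
    log_dens = -0.5 * (np.log(2.0 * np.pi * var) + diff * diff / var)
    return np.log(model.priors)[None, :] + log_dens.sum(axis=2)


def predict_table(model: GaussianNBModel, X: np.ndarray) -> tuple:
    """Vectorized prediction; returns (labels, posterior matrix)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lj = _log_joint(model, X)
    lj -= lj.max(axis=1, keepdims=True)
    post = np.exp(lj)
    post /= post.sum(axis=1, keepdims=True)
    # argmax with ties broken by class declaration order (first max wins)
    labels = np.array([model.classes[i] for i in np.argmax(post, axis=1)], dtype=object)
    return labels, post


def predict_class(model: GaussianNBModel, x: Sequence[float]) -> tuple:
    """Predict one feature vector; returns (label, {class: posterior})."""
    labels, post = predict_table(model, np.asarray(x, dtype=float)[None, :])
    return labels[0], dict(zip(model.classes, post[0]))


@dataclass(frozen=True)
class CVReport:
    k: int
    seed: int
    accuracy: float
    n_correct: int
    n_incorrect: int
    confusion: dict  # true class -> {predicted class -> count}

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "confusion": self.confusion,
        }


def _stratified_folds(y: np.ndarray, classes: tuple, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Assign each row a fold id; folds are as class-balanced as possible."""
    fold_of = np.empty(len(y), dtype=int)
    cursor = 0
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            fold_of[i] = cursor % k
            cursor += 1
    return fold_of


def _prior_only_predict(train_y: np.ndarray, classes: tuple, n: int) -> np.ndarray:
    counts = [(list(train_y).count(c), c) for c in classes]
    best = max(counts, key=lambda t: t[0])[1]
    return np.array([best] * n, dtype=object)


def cross_validate(
    table: LabeledFeatureTable,
    features: Optional[Sequence[str]] = None,
    k: int = 20,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the Gaussian NB classifier.

    The partition is a seeded stratified shuffle into ``k`` folds of sizes as
    equal as possible; each fold is predicted by a model fit on the remaining
    folds and held-out predictions are pooled into one accuracy.  With an
    empty feature list the majority-class prior is used (prior-only
    fallback).
    """
    if features is None:
        features = table.feature_names
    if k < 2 or k > table.n:
        raise ValueError("k must be in [2, n_rows]")
    sub = table.select(features) if len(features) else table
    classes = table.classes
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(table.y, classes, k, rng)

    pred = np.empty(table.n, dtype=object)
    for fold in range(k):
        test = fold_of == fold
        if not test.any():
            continue
        train = ~test
        train_classes = set(table.y[train])
        if len(features) == 0 or len(train_classes) < 2:
            if len(features) and len(train_classes) < 2:
                logger.warning(
                    "fold %d: training split lacks %s; prior-only fallback",
                    fold, set(classes) - train_classes,
                )
            pred[test] = _prior_only_predict(table.y[train], classes, int(test.sum()))
        else:
            model = fit_naive_bayes(sub.subset_rows(train))
            pred[test], _ = predict_table(model, sub.X[test])

    correct = int((pred == table.y).sum())
    confusion = {c: {c2: 0 for c2 in classes} for c in classes}
    for truth, guess in zip(table.y, pred):
        confusion[truth][guess] += 1
    return CVReport(
        k=k,
        seed=seed,
        accuracy=correct / table.n,
        n_correct=correct,
        n_incorrect=table.n - correct,
        confusion=confusion,
    )


@dataclass(frozen=True)
class SelectionResult:
    selected_features: tuple
    score: float
    search_trace: tuple  # ((features...), score) in evaluation order

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "score": self.score,
            "search_trace": [[list(f), s] for f, s in self.search_trace],
        }


def _subset_key(features: tuple) -> tuple:
    return (len(features), tuple(sorted(features)))


def select_features_best_first(
    table: LabeledFeatureTable,
    k: int = 20,
    seed: int = 0,
    stall_limit: int = 5,
) -> SelectionResult:
    """Forward best-first search over feature subsets scored by CV accuracy.

    The open list is ordered by score; the search stops after ``stall_limit``
    consecutive expansions that fail to improve on the best score found.
    Ties are broken in favor of smaller subsets, then lexicographic feature
    order.
    """
    if not table.feature_names:
        raise ValueError("table has no features")
    all_features = tuple(sorted(table.feature_names))
    scores: dict = {}

    def score(subset: tuple) -> float:
        if subset not in scores:
            scores[subset] = cross_validate(table, list(subset), k=k, seed=seed).accuracy
        return scores[subset]

    def better(cand: tuple, cand_score: float, best: tuple, best_score: float) -> bool:
        if cand_score != best_score:
            return cand_score > best_score
        return _subset_key(cand) < _subset_key(best)

    empty: tuple = ()
    s0 = score(empty)
    trace = [(empty, s0)]
    best, best_score = empty, s0

    counter = 0
    open_list: list = [(-s0, _subset_key(empty), counter, empty)]
    closed: set = {empty}
    stall = 0
    while open_list and stall < stall_limit:
        _, _, _, node = heapq.heappop(open_list)
        improved = False
        for f in all_features:
            if f in node:
                continue
            child = tuple(sorted(node + (f,)))
            if child in closed:
                continue
            closed.add(child)
            s = score(child)
            trace.append((child, s))
            if better(child, s, best, best_score):
                best, best_score = child, s
                improved = True
            counter += 1
            heapq.heappush(open_list, (-s, _subset_key(child), counter, child))
        stall = 0 if improved else stall + 1
    return SelectionResult(best, best_score, tuple(trace))
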