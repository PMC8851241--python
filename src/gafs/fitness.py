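"""Classifier-hits fitness under stratified k-fold cross-validation.

The wrapper evaluates a candidate feature subset by training a simple
classifier (1-nearest-neighbor by default, or Gaussian naive Bayes) on the
subset's columns and counting correct predictions over a k-fold partition.
The hit count — not an averaged rate — is the fitness: an integer bounded by
the number of subjects, directly comparable across subsets as long as the
fold partition is held fixed.

Prediction is implemented directly on numpy arrays because fitness must be a
pure deterministic function of (table, subset, folds): distance ties resolve
to the lowest training-row index, KNN vote ties to the class of the single
nearest neighbor, and naive-Bayes posterior ties to the class earliest in
sorted label order. Per-class per-feature variances are floored to keep
likelihoods finite on constant features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import FoldError
from .feature_table import FeatureTable
from ._util import round_half_up

__all__ = [
    "ClassifierSpec",
    "choose_k",
    "stratified_folds",
    "kfold_hits",
    "fitness_rate",
    "fit_predict",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which wrapped classifier scores a feature subset.

    kind: ``"knn"`` or ``"gaussian_nb"``; knn_k: neighbor count (default 1);
    distance: only ``"euclidean"`` is supported; variance_floor: lower bound on
    per-class per-feature variance in the naive-Bayes likelihood.
    """

    kind: str = "knn"
    knn_k: int = 1
    distance: str = "euclidean"
    variance_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "gaussian_nb"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.distance != "euclidean":
            raise ValueError(f"unsupported distance {self.distance!r}")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")


def choose_k(n_instances: int, threshold: int = 100) -> int:
    """Fold-count rule: 5 folds for larger datasets, 3 for smaller ones.

    Returns 5 when ``n_instances >= threshold`` (default 100), else 3. Fewer
    than 6 instances cannot form three folds of at least two subjects.
    """
    if n_instances < 6:
        raise ValueError(f"need at least 6 instances for 3-fold CV, got {n_instances}")
    return 5 if n_instances >= threshold else 3


def stratified_folds(labels: Sequence[str], k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each instance to one of k folds, stratified by label.

    Per-class fold occupancies differ by at most one, so small minority groups
    appear in every test fold. Returns an int array of fold ids, length M.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = np.unique(labels)[counts.argmin()]
        raise FoldError(
            f"class {small!r} has {counts.min()} members, fewer than k={k} folds"
        )
    seed = int(rng.integers(0, 2**31 - 1))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold_id, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold_id
    return assignment


def _knn_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    # squared Euclidean distances; monotone in the metric so argsort order is identical
    d2 = ((x_test[:, None, :] - x_train[None, :, :]) ** 2).sum(axis=2)
    # stable sort: among equal distances the lower training-row index comes first
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    neighbor_labels = y_train[order]
    if k == 1:
        return neighbor_labels[:, 0]
    classes = np.unique(y_train)
    votes = (neighbor_labels[:, :, None] == classes[None, None, :]).sum(axis=1)
    best = votes.max(axis=1, keepdims=True)
    out = np.empty(x_test.shape[0], dtype=y_train.dtype)
    for i in range(x_test.shape[0]):
        tied = classes[votes[i] == best[i]]
        # vote tie -> side with the single nearest neighbor if it is among the tied
        nearest = neighbor_labels[i, 0]
        out[i] = nearest if nearest in tied else tied[0]
    return out


def _gnb_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    variance_floor: float,
) -> np.ndarray:
    classes = np.unique(y_train)  # sorted: argmax ties fall to the earlier class
    log_joint = np.empty((x_test.shape[0], classes.size))
    m = y_train.size
    for ci, c in enumerate(classes):
        xc = x_train[y_train == c]
        mu = xc.mean(axis=0)
        var = np.maximum(xc.var(axis=0, ddof=0), variance_floor)
        ll = -0.5 * (np.log(2 * np.pi * var) + (x_test - mu) ** 2 / var).sum(axis=1)
        log_joint[:, ci] = ll + np.log(xc.shape[0] / m)
    return classes[np.argmax(log_joint, axis=1)]


def fit_predict(
    x_train: np.ndarray,
    y_train: Sequence[str],
    x_test: np.ndarray,
    spec: ClassifierSpec,
) -> np.ndarray:
    """Train the wrapped classifier once and predict test labels.

    A degenerate training set with a single class predicts that class for
    every test instance (both classifiers reduce to this naturally).
    """
    y_train = np.asarray(y_train)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(y_train).size == 1:
        return np.full(x_test.shape[0], y_train[0], dtype=y_train.dtype)
    if spec.kind == "knn":
        k = min(spec.knn_k, x_train.shape[0])
        return _knn_predict(x_train, y_train, x_test, k)
    return _gnb_predict(x_train, y_train, x_test, spec.variance_floor)


def kfold_hits(
    table: FeatureTable,
    subset: Sequence[int],
    spec: ClassifierSpec,
    folds: np.ndarray,
) -> int:
    """Cross-validated hit count of a feature subset: the GA's fitness.

    Each fold is predicted once by a classifier trained on the remaining
    folds restricted to the subset's columns; hits sum over folds, so
    0 <= hits <= M.
    """
    cols = np.asarray(list(subset), dtype=int)
    if cols.size == 0:
        raise ValueError("empty feature subset")
    if cols.min() < 0 or cols.max() >= table.n_regions:
        raise ValueError("subset indices out of range for table")
    x = table.values[:, cols]
    y = np.asarray(table.labels)
    folds = np.asarray(folds)
    hits = 0
    for fold_id in np.unique(folds):
        test = folds == fold_id
        pred = fit_predict(x[~test], y[~test], x[test], spec)
        hits += int((pred == y[test]).sum())
    return hits


def fitness_rate(hits: float, n_instances: int) -> float:
    """Hits as a percentage of instances, half-up rounded to two decimals.

    Accepts fractional hits so that multi-trial mean hit counts convert the
    same way as single-run integers (e.g. 115.11 of 127 -> 90.64)."""
    if not (0 <= hits <= n_instances):
        raise ValueError(f"hits {hits} outside [0, {n_instances}]")
    return round_half_up(100.0 * hits / n_instances)
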