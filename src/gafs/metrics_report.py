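"""Reporting quantities, multi-trial averaging and external validation.

Two derived percentages summarize every solution: the fitness rate (hits as a
percentage of subjects) and the cutting rate, 100 * (N - L) / N, the share of
the N-region feature pool a solution with L selected regions discards.
Multi-trial summaries average fitness and feature counts arithmetically over
repeated seeded runs; because the cutting rate is linear in the feature count,
the cutting rate of the mean count equals the mean of per-trial cutting rates.
All percentages are half-up rounded to two decimals at presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import SchemaError
from .feature_table import FeatureTable
from .fitness import ClassifierSpec, fit_predict
from ._util import round_half_up

if TYPE_CHECKING:  # pragma: no cover
    from .ga_engine import SolutionReport

__all__ = [
    "cutting_rate",
    "confusion_metrics",
    "external_validate",
    "average_trials",
    "TrialSummary",
    "ValidationResult",
]


def cutting_rate(n_selected: float, n_total: int) -> float:
    """Percentage of the feature pool discarded by a solution.

    ``100 * (n_total - n_selected) / n_total``, half-up rounded to two
    decimals; fractional ``n_selected`` supports trial-averaged feature
    counts (e.g. 47.96 of 116 -> 58.66).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 < n_selected <= n_total):
        raise ValueError(f"n_selected {n_selected} outside (0, {n_total}]")
    return round_half_up(100.0 * (n_total - n_selected) / n_total)


@dataclass(frozen=True)
class ConfusionMetrics:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    degenerate: tuple[str, ...] = ()  # metrics whose denominator was zero

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def confusion_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], positive: str
) -> ConfusionMetrics:
    """Binary quality metrics one-vs-rest for the requested positive class.

    accuracy, precision, sensitivity (recall), specificity and F1 from the
    TP/FP/FN/TN counts; a zero denominator yields 0.0 and the metric's name in
    ``degenerate``. Multi-class inputs are reduced to positive-vs-rest.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if positive not in set(y_true) | set(y_pred):
        raise ValueError(f"positive label {positive!r} absent from inputs")
    t, p = y_true == positive, y_pred == positive
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())

    degenerate: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / len(y_true)
    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    return ConfusionMetrics(accuracy, precision, sensitivity, specificity, f1, tuple(degenerate))


@dataclass
class ValidationResult:
    """Predictions on an external cohort plus per-class and macro metrics."""

    predictions: list[str]
    per_class: dict[str, ConfusionMetrics]
    macro: dict[str, float]


def external_validate(
    train: FeatureTable,
    test: FeatureTable,
    subset: Sequence[int],
    spec: ClassifierSpec,
) -> ValidationResult:
    """Fit a fixed selected-feature model on one cohort, score another.

    ``subset`` indexes the TRAINING atlas; test columns are matched by region
    name, so the external table may order its columns differently or carry
    extra regions. The
    classifier is trained once on the full training table (no CV) and applied
    to every test row.
    """
    cols = [int(c) for c in subset]
    names = [train.atlas.names[c] for c in cols]
    missing = [nm for nm in names if nm not in test.atlas.names]
    if missing:
        raise SchemaError(f"test table lacks selected regions: {missing}")
    test_cols = [test.atlas.index_of(nm) for nm in names]
    pred = fit_predict(train.values[:, cols], train.labels, test.values[:, test_cols], spec)
    predictions = [str(x) for x in pred]
    per_class = {
        lab: confusion_metrics(test.labels, predictions, lab)
        for lab in sorted(set(test.labels))
    }
    macro = {
        key: float(np.mean([m.as_dict()[key] for m in per_class.values()]))
        for key in ("accuracy", "precision", "sensitivity", "specificity", "f1")
    }
    return ValidationResult(predictions, per_class, macro)


@dataclass(frozen=True)
class TrialSummary:
    """Row of a trial-averaged results table for one task x classifier pair."""

    task: str
    classifier_kind: str
    mean_fitness: float
    mean_fitness_rate: float
    mean_features: float
    mean_cutting_rate: float
    n_trials: int


def average_trials(reports: Sequence["SolutionReport"], task: str = "") -> TrialSummary:
    """Average repeated seeded runs into one summary row.

    Fitness, fitness rate and feature count are arithmetic means over trials;
    the cutting rate is computed from the mean feature count (identical to the
    mean per-trial cutting rate, by linearity). Rounding happens here, at
    presentation.
    """
    if not reports:
        raise ValueError("no reports to average")
    kinds = {r.classifier_kind for r in reports}
    ns = {r.n_regions for r in reports}
    ms = {r.n_instances for r in reports}
    if len(kinds) > 1 or len(ns) > 1 or len(ms) > 1:
        raise ValueError("reports mix classifiers or task shapes; average one task at a time")
    n_total = reports[0].n_regions
    m = reports[0].n_instances
    mean_fitness = float(np.mean([r.fitness for r in reports]))
    mean_features = float(np.mean([len(r.selected_indices) for r in reports]))
    return TrialSummary(
        task=task,
        classifier_kind=reports[0].classifier_kind,
        mean_fitness=round_half_up(mean_fitness),
        mean_fitness_rate=round_half_up(100.0 * mean_fitness / m),
        mean_features=round_half_up(mean_features),
        mean_cutting_rate=cutting_rate(mean_features, n_total),
        n_trials=len(reports),
    )
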