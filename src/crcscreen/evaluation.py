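"""Confusion-matrix metrics, ROC sweep and AUC for slide triage.

High risk is the positive class throughout (the screening framing:
sensitivity is the rate at which diseased slides are caught). Rates whose
denominator is empty are reported as missing (``None``), never coerced to
zero. The AUC is computed by sweeping every distinct score as a threshold
and integrating the ROC by the trapezoid rule, which (with tied scores
grouped) equals the pairwise concordance statistic with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError
from .types import RiskLabel


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    """Confusion counts plus the derived triage metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    auc: float | None = None
    roc: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "roc": [list(point) for point in self.roc],
        }


def _check_ids(predictions: Mapping, truths: Mapping) -> list:
    pred_ids, truth_ids = set(predictions), set(truths)
    if pred_ids != truth_ids:
        missing = sorted(truth_ids - pred_ids)
        extra = sorted(pred_ids - truth_ids)
        raise InputError(
            f"prediction/truth slide ids differ (missing={missing}, extra={extra})"
        )
    return sorted(pred_ids)


def confusion(
    predictions: Mapping[str, RiskLabel | str], truths: Mapping[str, RiskLabel | str]
) -> ConfusionCounts:
    """Exact confusion counts over matching slide-id sets."""
    ids = _check_ids(predictions, truths)
    tp = tn = fp = fn = 0
    for slide_id in ids:
        pred = RiskLabel(predictions[slide_id])
        truth = RiskLabel(truths[slide_id])
        if truth is RiskLabel.HIGH:
            if pred is RiskLabel.HIGH:
                tp += 1
            else:
                fn += 1
        else:
            if pred is RiskLabel.HIGH:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Sensitivity, specificity, accuracy and F1 from confusion counts.

    Undefined rates (no positives / no negatives / no predicted positives)
    are reported as ``None``.
    """
    if counts.total == 0:
        raise InputError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    accuracy = (tp + tn) / counts.total
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sensitivity, specificity=specificity,
        accuracy=accuracy, f1=f1,
    )


def roc_auc(
    scores: Mapping[str, float], truths: Mapping[str, RiskLabel | str]
) -> tuple[float, list[tuple[float, float, float]]]:
    """ROC sweep over all distinct scores and trapezoid AUC.

    Returns ``(auc, [(threshold, sensitivity, 1 - specificity), ...])``
    with the degenerate (+inf, 0, 0) starting point included. Tied scores
    enter the sweep as one step, so the trapezoid integral equals the
    concordance probability with ties counted one half. Requires both
    classes present.
    """
    ids = _check_ids(scores, truths)
    y = np.array([1 if RiskLabel(truths[i]) is RiskLabel.HIGH else 0 for i in ids])
    s = np.array([float(scores[i]) for i in ids])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    points: list[tuple[float, float, float]] = [(float("inf"), 0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(ids)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            if y_sorted[j] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((float(s_sorted[i]), tp / n_pos, fp / n_neg))
        i = j
    fpr = np.array([pt[2] for pt in points])
    tpr = np.array([pt[1] for pt in points])
    auc = float(np.trapezoid(tpr, fpr))
    return auc, points


def solve_confusion_counts(
    n_correct: int,
    fp: int,
    fn: int,
    sensitivity_pct: float,
    specificity_pct: float,
    decimals: int = 1,
) -> ConfusionCounts:
    """Recover the unique confusion matrix behind a published error profile.

    Given the number of correctly classified slides, the false-positive and
    false-negative counts, and sensitivity/specificity printed to
    ``decimals`` decimal places (percent scale), integer-search the TP/TN
    split consistent with all of them. Raises if no split or more than one
    split matches.
    """
    solutions = []
    for tp in range(n_correct + 1):
        tn = n_correct - tp
        if tp + fn == 0 or tn + fp == 0:
            continue
        sens = round(100.0 * tp / (tp + fn), decimals)
        spec = round(100.0 * tn / (tn + fp), decimals)
        if sens == round(sensitivity_pct, decimals) and spec == round(
            specificity_pct, decimals
        ):
            solutions.append(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    if len(solutions) != 1:
        raise InputError(
            f"expected exactly one confusion matrix, found {len(solutions)}"
        )
    return solutions[0]


def evaluate(
    predictions: Mapping[str, RiskLabel | str],
    truths: Mapping[str, RiskLabel | str],
    scores: Mapping[str, float] | None = None,
) -> EvaluationReport:
    """Full report: confusion counts, rates, and (when scores given) ROC/AUC."""
    report = metrics(confusion(predictions, truths))
    if scores is not None:
        report.auc, report.roc = roc_auc(scores, truths)
    return report
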