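"""Predicted efficiency as a binary classifier of PCR success.

A reaction counts as a success when its measured efficiency reaches the
chosen threshold (default 1.65, i.e. 65% efficiency: reactions strictly
below fail).  Predicted efficiency is then scored as a ranking of
successes via ROC and precision-recall curves, swept over a small set of
experimentally motivated thresholds (1.60, 1.65, and the 1.80 boundary
often quoted for optimized reactions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import ConfigurationError, UndefinedCurveError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PRCurve",
    "ROCCurve",
    "ThresholdedDataset",
    "label_success",
    "pr_curve",
    "roc_curve",
    "threshold_sweep",
]

DEFAULT_THRESHOLDS = (1.60, 1.65, 1.80)
SUCCESS_THRESHOLD = 1.65


def label_success(measured, threshold: float = SUCCESS_THRESHOLD) -> np.ndarray:
    """Success labels: measured efficiency >= threshold (below fails).

    A threshold outside the open (1, 2) efficiency range is allowed but
    warned about, since it can only produce a single class.
    """
    measured = np.asarray(measured, dtype=float)
    if np.any((measured < 1.0) | (measured > 2.0)):
        raise ConfigurationError("measured efficiencies must lie in [1, 2]")
    if not 1.0 < threshold < 2.0:
        warnings.warn(
            f"success threshold {threshold} lies outside the (1, 2) efficiency range"
        )
    return measured >= threshold


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class ThresholdedDataset:
    """Scores, measurements and the labels induced by one threshold."""

    predicted: np.ndarray
    measured: np.ndarray
    threshold: float
    labels: np.ndarray

    @classmethod
    def from_measurements(cls, predicted, measured, threshold=SUCCESS_THRESHOLD):
        predicted = np.asarray(predicted, dtype=float)
        measured = np.asarray(measured, dtype=float)
        if len(predicted) != len(measured):
            raise ConfigurationError("predicted and measured must be aligned")
        return cls(predicted, measured, threshold, label_success(measured, threshold))


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise UndefinedCurveError(
            "ROC/PR curves need at least one positive and one negative label"
        )
    return labels


def roc_curve(scores, labels) -> ROCCurve:
    """ROC points at every distinct score plus the (0,0)/(1,1) endpoints.

    Tied scores are grouped into one operating point; AUC is the trapezoid
    area, which for a ranking score equals U/(n1*n0) of the two-sample
    Mann-Whitney statistic.
    """
    labels = _check_two_classes(labels)
    fpr, tpr, thr = _skm.roc_curve(labels, np.asarray(scores, dtype=float),
                                   drop_intermediate=False)
    return ROCCurve(fpr, tpr, thr, float(_skm.auc(fpr, tpr)))


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall points in increasing-recall order.

    One point per distinct score threshold (positive when score >= t),
    swept from the top score down until full recall is first reached;
    lower thresholds only dilute precision at the same recall.  Precision
    at zero predicted positives (recall 0) is 1 by convention.  Degenerate
    all-positive labels give precision identically 1.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not labels.any():
        raise UndefinedCurveError("PR curve needs at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    tp = np.cumsum(l_sorted)
    npred = np.arange(1, len(scores) + 1)
    last_of_score = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    keep = np.flatnonzero(last_of_score)
    total_pos = int(labels.sum())
    full = np.searchsorted(tp[keep], total_pos)  # first threshold at full recall
    keep = keep[: full + 1]
    recall = tp[keep] / total_pos
    precision = tp[keep] / npred[keep]
    return PRCurve(
        np.r_[0.0, recall],
        np.r_[1.0, precision],
        np.r_[np.inf, s_sorted[keep]],
    )


def threshold_sweep(
    predicted, measured, thresholds=DEFAULT_THRESHOLDS
) -> tuple[pd.DataFrame, dict[float, dict]]:
    """ROC/PR curves for each success threshold.

    Thresholds that give a single class are skipped with a warning.
    Returns a summary table (one row per usable threshold, sorted by ROC
    AUC, descending) and a dict threshold -> {"roc": ROCCurve, "pr":
    PRCurve, "dataset": ThresholdedDataset}.
    """
    predicted = np.asarray(predicted, dtype=float)
    rows = []
    curves: dict[float, dict] = {}
    for thr in thresholds:
        ds = ThresholdedDataset.from_measurements(predicted, measured, thr)
        try:
            roc = roc_curve(ds.predicted, ds.labels)
            pr = pr_curve(ds.predicted, ds.labels)
        except UndefinedCurveError:
            warnings.warn(f"threshold {thr}: a single class only, skipped")
            continue
        curves[thr] = {"roc": roc, "pr": pr, "dataset": ds}
        rows.append(
            {
                "threshold": thr,
                "auc_roc": roc.auc,
                "n_pos": int(ds.labels.sum()),
                "n_neg": int((~ds.labels).sum()),
            }
        )
    table = pd.DataFrame(rows, columns=["threshold", "auc_roc", "n_pos", "n_neg"])
    if len(table):
        table = table.sort_values("auc_roc", ascending=False).reset_index(drop=True)
    return table, curves
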