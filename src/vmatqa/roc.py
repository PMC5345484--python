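"""ROC analysis of complexity as a QA-failure predictor.

A plan is flagged positive when its complexity is strictly above the
threshold.  A positive that failed pretreatment QA is a true positive; a
positive that passed is a false positive.  The curve is the empirical step
function obtained by sweeping the threshold over the observed complexities;
no smoothing or parametric fit is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import CohortRecord

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "confusion_at_threshold",
    "roc_curve",
    "recommend_threshold",
    "SingleClassError",
    "percent",
]


class SingleClassError(ValueError):
    """The labeled cohort lacks failing or passing plans."""


def percent(fraction: float) -> int:
    """Round a fraction to a whole percent, half-up (0.435 -> 44)."""
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def tpr_percent(self) -> int:
        return percent(self.tpr)

    @property
    def fpr_percent(self) -> int:
        return percent(self.fpr)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "fpr": self.fpr,
            "tpr_percent": self.tpr_percent, "fpr_percent": self.fpr_percent,
        }


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep: ordered (threshold, fpr, tpr) triples plus AUC.

    Thresholds descend from +inf (fpr = tpr = 0) to -inf (fpr = tpr = 1);
    both rates are non-increasing in threshold.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _split_labeled(records: list[CohortRecord]) -> tuple[np.ndarray, np.ndarray]:
    failing = np.array([r.complexity for r in records if r.qa_pass is False])
    passing = np.array([r.complexity for r in records if r.qa_pass is True])
    if failing.size == 0 or passing.size == 0:
        raise SingleClassError(
            "ROC analysis needs at least one failing and one passing plan "
            f"(got {failing.size} failing, {passing.size} passing)"
        )
    return failing, passing


def confusion_at_threshold(records: list[CohortRecord], t: float) -> ConfusionCounts:
    """Confusion counts at a single threshold; positive = complexity > t."""
    failing, passing = _split_labeled(records)
    tp = int(np.count_nonzero(failing > t))
    fp = int(np.count_nonzero(passing > t))
    return ConfusionCounts(tp=tp, fp=fp, tn=passing.size - fp, fn=failing.size - tp)


def roc_curve(records: list[CohortRecord]) -> RocCurve:
    """Empirical ROC over thresholds at every distinct complexity plus sentinels.

    Pointwise identical to :func:`confusion_at_threshold` at each listed
    threshold; AUC by the trapezoid rule over the step curve.
    """
    failing, passing = _split_labeled(records)
    values = np.unique(np.concatenate([failing, passing]))  # ascending
    thresholds = np.concatenate([[np.inf], values[::-1], [-np.inf]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        tpr[i] = np.count_nonzero(failing > t) / failing.size
        fpr[i] = np.count_nonzero(passing > t) / passing.size
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def recommend_threshold(
    records: list[CohortRecord], max_fpr: float = 0.10
) -> tuple[float, ConfusionCounts, bool]:
    """Smallest candidate threshold whose FPR is strictly below ``max_fpr``.

    Both rates are non-increasing in the threshold, so the smallest
    compliant candidate also maximizes the TPR among compliant choices.
    Candidates are midpoints between adjacent distinct complexities plus a
    sentinel below the minimum and one above the maximum, so no datum ever
    sits exactly at the recommended threshold.

    Returns ``(threshold, counts, degenerate)`` where ``degenerate`` flags a
    recommendation that catches nothing (TPR = 0).
    """
    failing, passing = _split_labeled(records)
    values = np.unique(np.concatenate([failing, passing]))
    candidates = np.concatenate(
        [[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]]
    )
    for t in candidates:
        counts = confusion_at_threshold(records, float(t))
        if counts.fpr < max_fpr:
            return float(t), counts, counts.tp == 0
    raise AssertionError("unreachable: the top sentinel always has fpr 0")
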