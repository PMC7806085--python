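"""Detection-criterion calibration from the accuracy-vs-criterion curve.

Accuracy (fraction of trials decided correctly) is evaluated on a fixed grid
of 101 criteria c_j = 0.00, 0.01, ..., 1.00. The threshold criterion is read
off the curve: an accuracy threshold

    ACC_th = max_j ACC_j - (max_j ACC_j - 0.5) / 10

defines a lower and an upper qualifying criterion (the smallest and largest
c_j with ACC_j >= ACC_th); their midpoint is the detection criterion c_th.
At the extreme criteria (0 or 1) every balanced set scores the 0.5 chance
level, so the band around the peak is well defined whenever the model is
better than chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scoring import decide

__all__ = ["CRITERION_GRID", "AccCurve", "ThresholdResult", "acc_curve",
           "threshold_criterion"]

CRITERION_GRID: np.ndarray = np.arange(101) / 100.0


@dataclass(frozen=True)
class AccCurve:
    """Accuracy at each of the 101 grid criteria."""

    criteria: np.ndarray
    accuracies: np.ndarray

    def __post_init__(self) -> None:
        if len(self.criteria) != 101 or len(self.accuracies) != 101:
            raise ValueError("the criterion grid has 101 points")

    def to_table(self) -> "np.ndarray":
        return np.column_stack([self.criteria, self.accuracies])


@dataclass(frozen=True)
class ThresholdResult:
    """Calibrated criterion and the quantities that define it."""

    acc_threshold: float
    c_lower: float
    c_upper: float
    c_th: float


def acc_curve(scores: Sequence[float], truths: Sequence[bool]) -> AccCurve:
    """Accuracy of the strict-> decision rule over the criterion grid."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if scores.size == 0 or scores.shape != truths.shape:
        raise ValueError("scores and truths must be equal-length and non-empty")
    detected = scores[:, None] > CRITERION_GRID[None, :]
    acc = (detected == truths[:, None]).mean(axis=0)
    return AccCurve(criteria=CRITERION_GRID.copy(), accuracies=acc)


def threshold_criterion(curve: AccCurve) -> ThresholdResult:
    """Calibrate the detection criterion from an accuracy curve.

    The qualifying set {c_j : ACC_j >= ACC_th} is never empty because the
    maximiser qualifies; non-contiguous qualifying sets use the global
    smallest/largest member.
    """
    acc = np.asarray(curve.accuracies, dtype=float)
    peak = acc.max()
    if peak < 0.5:
        warnings.warn(
            "maximum accuracy below chance level (0.5): the model is "
            "degenerate; the criterion is still computed", stacklevel=2,
        )
    acc_th = peak - (peak - 0.5) / 10.0
    qualifying = np.flatnonzero(acc >= acc_th)
    if qualifying.size == 0:  # below-chance curve: acc_th exceeds the peak
        qualifying = np.flatnonzero(acc >= peak)
    c_l = float(curve.criteria[qualifying[0]])
    c_u = float(curve.criteria[qualifying[-1]])
    return ThresholdResult(acc_threshold=float(acc_th), c_lower=c_l,
                           c_upper=c_u, c_th=(c_l + c_u) / 2.0)
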