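"""Signal-detection-theoretic evaluation: hit/false-alarm rates, ROC, A_g.

Sweeping the detection criterion over the same 101-point grid used for
calibration yields pairs (F_j, H_j) of false-alarm and hit rates; connecting
them (with the (0,0) and (1,1) anchors) traces the empirical ROC curve, and
the trapezoidal area under it, A_g, measures potential sensitivity
independent of any particular criterion: 0.5 is chance, 1 is perfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .calibration import CRITERION_GRID

__all__ = ["RocCurve", "rates", "roc", "area_under_curve"]


@dataclass(frozen=True)
class RocCurve:
    """(F, H) pairs sorted by F (ties by H), anchors included."""

    false_alarm: np.ndarray
    hit: np.ndarray

    def __post_init__(self) -> None:
        f, h = self.false_alarm, self.hit
        if f.shape != h.shape or f.ndim != 1:
            raise ValueError("false_alarm and hit must be equal-length 1-D")
        if ((f < 0) | (f > 1) | (h < 0) | (h > 1)).any():
            raise ValueError("rates must lie in [0, 1]")

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.false_alarm, self.hit])


def rates(scores: Sequence[float], truths: Sequence[bool],
          criterion: float) -> Tuple[float, float]:
    """False-alarm and hit rate (F, H) at one criterion (strict-> rule)."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    n_present = int(truths.sum())
    n_absent = int((~truths).sum())
    if n_present == 0 or n_absent == 0:
        raise ValueError(
            "hit and false-alarm rates need at least one tumor-present and "
            "one tumor-absent trial"
        )
    detected = scores > criterion
    hit = detected[truths].sum() / n_present
    false_alarm = detected[~truths].sum() / n_absent
    return float(false_alarm), float(hit)


def roc(scores: Sequence[float], truths: Sequence[bool]) -> RocCurve:
    """Empirical ROC over the criterion grid, anchored at (0,0) and (1,1)."""
    pairs = {rates(scores, truths, c) for c in CRITERION_GRID}
    pairs.update({(0.0, 0.0), (1.0, 1.0)})
    ordered = sorted(pairs)
    f = np.array([p[0] for p in ordered])
    h = np.array([p[1] for p in ordered])
    return RocCurve(false_alarm=f, hit=h)


def area_under_curve(curve: RocCurve, literal: bool = False) -> float:
    """Area A_g under the ROC curve by the trapezoid rule.

    ``literal=True`` evaluates the product-of-differences variant
    ``1/2 * sum (F_{j+1}-F_j)(H_{j+1}-H_j)`` instead (documented for
    comparison; it vanishes on a unit-square curve and is not a valid area).
    """
    f, h = curve.false_alarm, curve.hit
    if (np.diff(f) < 0).any():
        raise ValueError("ROC curve must be sorted by false-alarm rate")
    df = np.diff(f)
    if literal:
        return float(0.5 * (df * np.diff(h)).sum())
    return float(0.5 * (df * (h[1:] + h[:-1])).sum())
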