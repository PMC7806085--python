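"""Fusion of overlapping window outputs into trial-level detection scores.

The network emits one probability vector per window; overlapping windows are
fused by averaging, per sample, over every window that covers it (ten in
steady state with the default 1.0 s / 0.9 s extraction). The maximum fused
score within each scanning interval is taken, and the mean of those maxima
is the trial's representative score. A trial is declared tumor-positive when
the representative score strictly exceeds the detection criterion.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .windowing import ExtractionConfig, ScanSegment, n_windows

__all__ = [
    "per_sample_scores",
    "scan_maxima",
    "representative_score",
    "decide",
]


class NoScanError(ValueError):
    """Raised when a trial has no scanning segment and cannot be scored."""


def per_sample_scores(window_outputs: np.ndarray, cfg: ExtractionConfig,
                      length: int) -> np.ndarray:
    """Per-sample mean probability over all covering windows.

    ``window_outputs`` must be the (n_windows, W) outputs for the windows of
    a trial of ``length`` samples, in extraction order. The result spans the
    covered region, i.e. ``(n_windows - 1) * shift + W`` samples; edge
    samples covered by fewer than the steady-state number of windows are
    averaged over however many windows cover them.
    """
    Y = np.asarray(window_outputs, dtype=float)
    w, s = cfg.window_samples, cfg.shift_samples
    expected = n_windows(length, cfg)
    if Y.ndim != 2 or Y.shape[0] != expected or Y.shape[1] != w:
        raise ValueError(
            f"window outputs of shape {Y.shape} inconsistent with trial "
            f"length {length} (expected ({expected}, {w}))"
        )
    covered = (expected - 1) * s + w
    sums = np.zeros(covered)
    counts = np.zeros(covered)
    for k in range(expected):
        sums[k * s:k * s + w] += Y[k]
        counts[k * s:k * s + w] += 1
    return sums / counts


def scan_maxima(scores: np.ndarray, segments: Sequence[ScanSegment]) -> List[float]:
    """Maximum fused score within each scanning segment, order preserved.

    Segments may extend past the covered region (windowing drops a partial
    trailing window); the overlap with the scored region is used.
    """
    if len(segments) == 0:
        raise NoScanError("trial has no scanning segments; it cannot be scored")
    scores = np.asarray(scores, dtype=float)
    maxima = []
    for seg in segments:
        a, b = seg.start, min(seg.end, len(scores))
        if a >= b:
            raise ValueError(f"segment [{seg.start}, {seg.end}) lies outside the scored region")
        maxima.append(float(scores[a:b].max()))
    return maxima


def representative_score(maxima: Sequence[float]) -> float:
    """Mean of the per-scan maxima — the trial's single detection score."""
    if len(maxima) == 0:
        raise NoScanError("no scan maxima; trial cannot be scored")
    return float(np.mean(maxima))


def decide(representative: float, criterion: float) -> bool:
    """Detection rule: tumor detected iff score strictly exceeds criterion."""
    return representative > criterion
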