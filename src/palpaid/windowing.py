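"""Sliding-window extraction and scanning-time segmentation.

The sensor trace is cut into fixed-width windows of ``t_window`` seconds
shifted by ``t_window - t_overlap`` (defaults 1.0 s / 0.9 s, i.e. a 10 Hz
refresh of the estimate and, in steady state, ten windows covering every
sample). Scanning intervals — the times the probe is actually in scanning
contact — are recovered from the tangential contact force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .synthetic import TrialRecord

__all__ = [
    "ExtractionConfig",
    "WindowPair",
    "ScanSegment",
    "extract_windows",
    "window_matrices",
    "n_windows",
    "coverage_counts",
    "extract_scan_segments",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Window width / overlap (seconds) and the trace sampling rate (Hz)."""

    t_window: float = 1.0
    t_overlap: float = 0.9
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_overlap < self.t_window):
            raise ValueError("need 0 <= t_overlap < t_window")
        for name in ("window_samples", "shift_samples"):
            getattr(self, name)  # triggers integrality checks

    @property
    def window_samples(self) -> int:
        w = self.t_window * self.sampling_rate
        if abs(w - round(w)) > 1e-9 or round(w) < 1:
            raise ValueError("t_window * sampling_rate must be a positive integer")
        return int(round(w))

    @property
    def shift_samples(self) -> int:
        s = (self.t_window - self.t_overlap) * self.sampling_rate
        if abs(s - round(s)) > 1e-9 or round(s) < 1:
            raise ValueError(
                "(t_window - t_overlap) * sampling_rate must be a positive integer"
            )
        return int(round(s))


@dataclass(frozen=True)
class WindowPair:
    """A sensor window ``x`` with its aligned binary label window ``t``."""

    x: np.ndarray
    t: np.ndarray
    start_index: int


@dataclass(frozen=True, order=True)
class ScanSegment:
    """Half-open sample interval [start, end) of one scanning stroke."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("segment must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


def n_windows(length: int, cfg: ExtractionConfig) -> int:
    """Number of full windows placed at offsets 0, s, 2s, ... in a trace."""
    w, s = cfg.window_samples, cfg.shift_samples
    if length < w:
        return 0
    return (length - w) // s + 1


def extract_windows(trial: TrialRecord, cfg: ExtractionConfig) -> List[WindowPair]:
    """Extract all full (sensor, label) window pairs from a trial.

    Windows start every ``shift_samples``; trailing samples that do not fill
    a complete window are not padded into partial windows (the model input
    dimension is fixed).
    """
    w, s = cfg.window_samples, cfg.shift_samples
    L = len(trial)
    if L < w:
        raise ValueError(
            f"trial of {L} samples is shorter than one window ({w} samples); "
            "no windows can be extracted"
        )
    return [
        WindowPair(x=trial.sensor[k * s:k * s + w],
                   t=trial.tumor_label[k * s:k * s + w],
                   start_index=k * s)
        for k in range(n_windows(L, cfg))
    ]


def window_matrices(trial: TrialRecord, cfg: ExtractionConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked window arrays ``(X, T, starts)`` with shapes (n, W), (n, W), (n,)."""
    pairs = extract_windows(trial, cfg)
    X = np.stack([p.x for p in pairs])
    T = np.stack([p.t for p in pairs]).astype(float)
    starts = np.array([p.start_index for p in pairs])
    return X, T, starts


def coverage_counts(length: int, cfg: ExtractionConfig) -> np.ndarray:
    """Per-sample count of windows covering each of the ``length`` samples.

    In steady state this equals t_window / (t_window - t_overlap) (ten with
    the defaults); it ramps up from 1 at the first sample and back down at
    the trial edges. Samples past the last full window have count zero.
    """
    w, s = cfg.window_samples, cfg.shift_samples
    if length < w:
        raise ValueError("trace shorter than one window")
    counts = np.zeros(length, dtype=int)
    for k in range(n_windows(length, cfg)):
        counts[k * s:k * s + w] += 1
    return counts


def extract_scan_segments(
    trial: TrialRecord,
    threshold_fraction: float = 0.1,
    min_duration: float = 0.3,
    merge_gap: float = 0.1,
) -> List[ScanSegment]:
    """Extract scanning intervals from the tangential-force trace.

    Maximal runs where the force exceeds ``threshold_fraction`` of the
    trial's peak force are kept if they last at least ``min_duration``
    seconds; runs separated by gaps shorter than ``merge_gap`` seconds are
    merged first. An all-zero force trace yields no segments.
    """
    force = np.asarray(trial.tangential_force, dtype=float)
    if force.min() < 0:
        raise ValueError("tangential force must be non-negative")
    peak = force.max()
    if peak <= 0:
        return []
    fs = trial.sampling_rate
    above = force > threshold_fraction * peak
    runs = _runs(above)
    # merge across short gaps
    merged: List[List[int]] = []
    max_gap = int(round(merge_gap * fs))
    for start, end in runs:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    min_len = int(round(min_duration * fs))
    return [ScanSegment(a, b) for a, b in merged if b - a >= min_len]


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, end) intervals of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))
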