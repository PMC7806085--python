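"""Trial-level tumor detector: windowing + network + fusion + criterion.

``TumorDetector`` composes the full pipeline behind a scikit-learn style
interface: ``fit`` trains the window segmentation network on a set of
trials, ``calibrate`` determines the detection criterion on a separate set
of trials, and ``predict`` returns the per-trial detection decision.
Keeping the two stages separate mirrors how the method is validated: model
parameters must depend only on the training trials and the criterion only
on the calibration trials.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, clone

from .calibration import acc_curve, threshold_criterion
from .network import WindowSegmenterMLP
from .scoring import per_sample_scores, representative_score, scan_maxima
from .sdt import area_under_curve, roc
from .synthetic import TrialRecord
from .windowing import (ExtractionConfig, ScanSegment, extract_scan_segments,
                        window_matrices)

__all__ = ["TumorDetector", "trial_segments", "trial_score_series"]


def trial_segments(trial: TrialRecord, use_true_segments: bool = False,
                   threshold_fraction: float = 0.1, min_duration: float = 0.3,
                   merge_gap: float = 0.1) -> List[ScanSegment]:
    """Scanning segments of a trial: detected from the tangential force, or
    the simulator's ground-truth stroke intervals when requested."""
    if use_true_segments:
        if not trial.true_segments:
            raise ValueError(
                f"trial {trial.participant_id}/{trial.trial_index} carries "
                "no ground-truth segments"
            )
        return [ScanSegment(a, b) for a, b in trial.true_segments]
    return extract_scan_segments(trial, threshold_fraction=threshold_fraction,
                                 min_duration=min_duration, merge_gap=merge_gap)


def trial_score_series(models: Sequence[WindowSegmenterMLP],
                       trial: TrialRecord,
                       extraction: ExtractionConfig) -> np.ndarray:
    """Fused per-sample score series, ensemble-averaged over ``models``."""
    X, _, _ = window_matrices(trial, extraction)
    series = [per_sample_scores(m.predict_proba(X), extraction, len(trial))
              for m in models]
    return np.mean(series, axis=0)


class TumorDetector(BaseEstimator):
    """End-to-end detector over palpation trials.

    Parameters
    ----------
    segmenter : WindowSegmenterMLP or None
        Template network; cloned at ``fit``. ``None`` uses the defaults.
    t_window, t_overlap : float
        Window width and overlap in seconds (the extraction settings); the
        sampling rate is taken from the trials.
    use_true_segments : bool
        Score inside the simulator's ground-truth stroke intervals instead
        of force-detected scanning segments (isolates scoring from
        segmentation in experiments).
    threshold_fraction, min_duration, merge_gap
        Scanning-segment detection settings (see
        :func:`palpaid.windowing.extract_scan_segments`).
    random_state : int or None
        Seed for the network when the template has none set.

    Attributes
    ----------
    segmenter_ : the fitted network
    extraction_ : ExtractionConfig resolved against the training trials
    criterion_ : calibrated detection criterion (after ``calibrate``)
    calibration_ : ThresholdResult
    acc_curve_ : AccCurve from the calibration trials
    """

    def __init__(self, segmenter: Optional[WindowSegmenterMLP] = None,
                 t_window: float = 1.0, t_overlap: float = 0.9,
                 use_true_segments: bool = False, threshold_fraction: float = 0.1,
                 min_duration: float = 0.3, merge_gap: float = 0.1,
                 random_state: Optional[int] = None):
        self.segmenter = segmenter
        self.t_window = t_window
        self.t_overlap = t_overlap
        self.use_true_segments = use_true_segments
        self.threshold_fraction = threshold_fraction
        self.min_duration = min_duration
        self.merge_gap = merge_gap
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------
    def _resolve_extraction(self, trials: Sequence[TrialRecord]) -> ExtractionConfig:
        rates = {t.sampling_rate for t in trials}
        if len(rates) != 1:
            raise ValueError(f"trials mix sampling rates: {sorted(rates)}")
        return ExtractionConfig(t_window=self.t_window, t_overlap=self.t_overlap,
                                sampling_rate=rates.pop())

    def fit(self, trials: Sequence[TrialRecord], y=None):
        """Train the segmentation network on all windows of ``trials``."""
        if len(trials) == 0:
            raise ValueError("at least one training trial is required")
        self.extraction_ = self._resolve_extraction(trials)
        mats = [window_matrices(t, self.extraction_) for t in trials]
        X = np.concatenate([m[0] for m in mats])
        T = np.concatenate([m[1] for m in mats])
        template = self.segmenter if self.segmenter is not None else WindowSegmenterMLP()
        self.segmenter_ = clone(template)
        if self.segmenter_.random_state is None:
            self.segmenter_.set_params(random_state=self.random_state)
        self.segmenter_.fit(X, T)
        return self

    # -- scoring ---------------------------------------------------------
    def _segments(self, trial: TrialRecord) -> List[ScanSegment]:
        return trial_segments(trial, use_true_segments=self.use_true_segments,
                              threshold_fraction=self.threshold_fraction,
                              min_duration=self.min_duration,
                              merge_gap=self.merge_gap)

    def score_series(self, trial: TrialRecord) -> np.ndarray:
        """Fused per-sample tumor-probability series for one trial."""
        self._check_fitted()
        return trial_score_series([self.segmenter_], trial, self.extraction_)

    def score_trials(self, trials: Sequence[TrialRecord]) -> np.ndarray:
        """Representative score (mean of per-scan maxima) per trial."""
        self._check_fitted()
        return np.array([
            representative_score(scan_maxima(self.score_series(t),
                                             self._segments(t)))
            for t in trials
        ])

    # -- criterion -------------------------------------------------------
    def calibrate(self, trials: Sequence[TrialRecord]):
        """Determine the detection criterion on calibration trials."""
        scores = self.score_trials(trials)
        truths = np.array([t.tumor_present for t in trials])
        self.acc_curve_ = acc_curve(scores, truths)
        self.calibration_ = threshold_criterion(self.acc_curve_)
        self.criterion_ = self.calibration_.c_th
        return self

    def predict(self, trials: Sequence[TrialRecord]) -> np.ndarray:
        """Boolean detection per trial (requires a calibrated criterion)."""
        if not hasattr(self, "criterion_"):
            raise AttributeError("call calibrate() before predict()")
        return self.score_trials(trials) > self.criterion_

    def evaluate(self, trials: Sequence[TrialRecord]) -> dict:
        """Accuracy at the calibrated criterion plus ROC area on trials."""
        scores = self.score_trials(trials)
        truths = np.array([t.tumor_present for t in trials])
        out = {"scores": scores, "truths": truths}
        if hasattr(self, "criterion_"):
            out["accuracy"] = float(((scores > self.criterion_) == truths).mean())
        curve = roc(scores, truths)
        out["roc"] = curve
        out["a_g"] = area_under_curve(curve)
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "segmenter_"):
            raise AttributeError("estimator is not fitted")
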