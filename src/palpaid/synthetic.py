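"""Synthetic phantom-scan generator.

Emulates laparoscopic palpation trials: a forceps-mounted tactile sensor is
stroked repeatedly over a silicone stomach-wall phantom. Each stroke produces
a contact bump in the sensor trace and a raised tangential contact force.
When the phantom carries the toroidal early-gastric-cancer mock-up, crossing
it adds the characteristic two-peak signature (one peak per tumor edge) and
the per-sample tumor label is 1 over the crossing interval. Traces are
sampled at ``sampling_rate`` and low-pass filtered (zero-phase Butterworth)
after additive Gaussian noise, mirroring the 10 Hz conditioning of the real
recordings.

The generator's defaults define the simulated study conditions: 40 trials
per participant (20 with the tumor, 20 without), a handful of strokes per
trial, and participant-to-participant variation in speed and applied force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ScanProfile",
    "TrialRecord",
    "generate_trial",
    "generate_participant",
    "generate_cohort",
    "desk_profile",
]

TRIALS_PER_PARTICIPANT = 40
_PRESENT_PER_PARTICIPANT = 20


@dataclass(frozen=True)
class ScanProfile:
    """Parameters of the simulated scanning behaviour for one participant.

    Amplitudes are in arbitrary sensor units (baseline contact bump ~1.0);
    durations in seconds; ``speed_jitter``/``force_jitter`` are relative
    standard deviations applied per stroke.
    """

    n_strokes: int = 3
    stroke_duration: float = 1.2
    baseline_force: float = 1.0
    tumor_peak_amplitude: float = 0.8
    tumor_peak_separation: float = 0.3
    noise_sd: float = 0.05
    sampling_rate: float = 1000.0
    lowpass_cutoff: float = 10.0
    speed_jitter: float = 0.1
    force_jitter: float = 0.1
    gap_range: Tuple[float, float] = (0.2, 0.5)
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_strokes < 1:
            raise ValueError("n_strokes must be >= 1")
        if self.sampling_rate <= 2 * self.lowpass_cutoff:
            raise ValueError(
                "sampling_rate must exceed twice the low-pass cutoff "
                f"(got fs={self.sampling_rate}, cutoff={self.lowpass_cutoff})"
            )
        for name in ("stroke_duration", "baseline_force", "tumor_peak_amplitude",
                     "tumor_peak_separation", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.gap_range[0] <= self.gap_range[1]):
            raise ValueError("gap_range must be positive and ordered")


def desk_profile(**overrides) -> ScanProfile:
    """Reduced-rate profile (50 Hz) for desk-scale runs; same phenomenology."""
    params = dict(sampling_rate=50.0)
    params.update(overrides)
    return ScanProfile(**params)


@dataclass
class TrialRecord:
    """One detection trial: traces, per-sample label and ground truth."""

    participant_id: str
    trial_index: int
    tumor_present: bool
    sensor: np.ndarray
    tumor_label: np.ndarray
    tangential_force: np.ndarray
    sampling_rate: float
    true_segments: Optional[List[Tuple[int, int]]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sensor = np.asarray(self.sensor, dtype=float)
        self.tumor_label = np.asarray(self.tumor_label)
        self.tangential_force = np.asarray(self.tangential_force, dtype=float)
        n = len(self.sensor)
        if len(self.tumor_label) != n or len(self.tangential_force) != n:
            raise ValueError("sensor, tumor_label and tangential_force must share length")
        if not np.isin(self.tumor_label, (0, 1)).all():
            raise ValueError("tumor_label must be binary")
        if not self.tumor_present and self.tumor_label.any():
            raise ValueError("tumor_label must be all-zero when tumor_present is False")

    def __len__(self) -> int:
        return len(self.sensor)


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    # 2nd-order zero-phase Butterworth: keeps labels aligned with peaks.
    sos = butter(2, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _jittered(value: float, rel_sd: float, rng: np.random.Generator,
              lo_frac: float = 0.3) -> float:
    # Draw is consumed even at zero jitter so geometry is identical across
    # jitter settings given the same stream position.
    z = rng.standard_normal()
    return max(value * (1.0 + rel_sd * z), value * lo_frac)


def generate_trial(
    profile: ScanProfile,
    tumor_present: bool,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "P00",
    trial_index: int = 0,
) -> TrialRecord:
    """Simulate a single detection trial.

    Each stroke contributes a half-sine contact bump to the sensor trace and
    a raised tangential-force interval. If ``tumor_present``, every stroke
    crosses the toroidal tumor once: two Gaussian peaks of width
    ``stroke_duration/10`` separated by ``tumor_peak_separation`` are added
    and the label is 1 from just before the first peak to just after the
    second. Noise is added and the sensor trace is then low-pass filtered.
    """
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    fs = profile.sampling_rate
    gap_mid = 0.5 * (profile.gap_range[0] + profile.gap_range[1])
    peak_width = profile.stroke_duration / 10.0
    sigma = peak_width / 2.0

    # Geometry first (all stochastic geometry is driven by the jitters so
    # that zero jitter yields a deterministic envelope).
    strokes = []
    cursor = max(_jittered(gap_mid, profile.speed_jitter, rng), profile.gap_range[0] * 0.5)
    for _ in range(profile.n_strokes):
        dur = _jittered(profile.stroke_duration, profile.speed_jitter, rng)
        amp = _jittered(profile.baseline_force, profile.force_jitter, rng, lo_frac=0.1)
        peak_amp = max(profile.tumor_peak_amplitude
                       * (1.0 + profile.force_jitter * rng.standard_normal()), 0.0)
        center_frac = float(np.clip(0.5 + profile.speed_jitter * rng.standard_normal(),
                                    0.3, 0.7))
        gap_after = max(_jittered(gap_mid, profile.speed_jitter, rng),
                        profile.gap_range[0] * 0.5)
        strokes.append((cursor, dur, amp, peak_amp, center_frac))
        cursor += dur + gap_after
    total = cursor + gap_mid
    n = int(round(total * fs))

    sensor = np.zeros(n)
    force = np.zeros(n)
    label = np.zeros(n, dtype=np.int8)
    t = np.arange(n) / fs
    true_segments: List[Tuple[int, int]] = []

    for start_s, dur, amp, peak_amp, center_frac in strokes:
        i0 = int(round(start_s * fs))
        i1 = min(int(round((start_s + dur) * fs)), n)
        if i1 <= i0:
            continue
        u = (np.arange(i0, i1) - i0) / max(i1 - i0, 1)
        bump = amp * np.sin(np.pi * u)
        sensor[i0:i1] += bump
        force[i0:i1] += bump
        true_segments.append((i0, i1))
        if tumor_present and peak_amp > 0:
            center = start_s + center_frac * dur
            p1 = center - profile.tumor_peak_separation / 2.0
            p2 = center + profile.tumor_peak_separation / 2.0
            for p in (p1, p2):
                sensor += peak_amp * np.exp(-0.5 * ((t - p) / sigma) ** 2)
            j0 = max(int(round((p1 - peak_width) * fs)), i0)
            j1 = min(int(round((p2 + peak_width) * fs)), i1)
            label[j0:j1] = 1

    sensor = sensor + rng.normal(0.0, profile.noise_sd, size=n)
    sensor = _lowpass(sensor, fs, profile.lowpass_cutoff)

    return TrialRecord(
        participant_id=participant_id,
        trial_index=trial_index,
        tumor_present=bool(tumor_present),
        sensor=sensor,
        tumor_label=label,
        tangential_force=force,
        sampling_rate=fs,
        true_segments=true_segments,
        meta={"profile": profile_to_dict(profile)},
    )


def generate_participant(
    profile: ScanProfile,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "P00",
) -> List[TrialRecord]:
    """Simulate the 40-trial session of one participant (20 tumor / 20 not),
    in randomized order."""
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    presence = np.array([True] * _PRESENT_PER_PARTICIPANT
                        + [False] * (TRIALS_PER_PARTICIPANT - _PRESENT_PER_PARTICIPANT))
    rng.shuffle(presence)
    return [
        generate_trial(profile, bool(p), rng,
                       participant_id=participant_id, trial_index=i)
        for i, p in enumerate(presence)
    ]


def generate_cohort(
    n_participants: int,
    base_profile: ScanProfile,
    inter_participant_sd: float = 0.15,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[TrialRecord]]:
    """Simulate a cohort; each participant scans with a perturbed profile.

    Applied force, scanning speed and the number of strokes vary between
    participants (relative SD ``inter_participant_sd``), emulating the
    between-user variation seen in real palpation sessions.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    base_profile.validate()
    if rng is None:
        rng = np.random.default_rng(base_profile.seed)
    cohort: Dict[str, List[TrialRecord]] = {}
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        if inter_participant_sd > 0:
            prof = replace(
                base_profile,
                baseline_force=_jittered(base_profile.baseline_force,
                                         inter_participant_sd, rng, lo_frac=0.2),
                tumor_peak_amplitude=_jittered(base_profile.tumor_peak_amplitude,
                                               inter_participant_sd, rng, lo_frac=0.2),
                stroke_duration=_jittered(base_profile.stroke_duration,
                                          inter_participant_sd, rng, lo_frac=0.5),
                n_strokes=max(1, base_profile.n_strokes + int(rng.integers(-1, 2))),
            )
        else:
            prof = base_profile
        cohort[pid] = generate_participant(prof, rng, participant_id=pid)
    return cohort


def profile_to_dict(profile: ScanProfile) -> dict:
    return {
        "n_strokes": profile.n_strokes,
        "stroke_duration": profile.stroke_duration,
        "baseline_force": profile.baseline_force,
        "tumor_peak_amplitude": profile.tumor_peak_amplitude,
        "tumor_peak_separation": profile.tumor_peak_separation,
        "noise_sd": profile.noise_sd,
        "sampling_rate": profile.sampling_rate,
        "lowpass_cutoff": profile.lowpass_cutoff,
        "speed_jitter": profile.speed_jitter,
        "force_jitter": profile.force_jitter,
        "gap_range": list(profile.gap_range),
        "seed": profile.seed,
    }


def profile_from_dict(d: dict) -> ScanProfile:
    d = dict(d)
    if "gap_range" in d:
        d["gap_range"] = tuple(d["gap_range"])
    return ScanProfile(**d)
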