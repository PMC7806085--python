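"""Trial storage, model serialization and configuration files.

Trials are stored as one CSV per trial (columns ``time_s``, ``sensor``,
``tangential_force``, ``tumor_label``) plus a single ``manifest.json``
carrying per-trial metadata (participant, index, ground truth, sampling
rate, ground-truth stroke segments and the generator profile/seed when
known). The format is versioned; unknown versions are rejected.

Model parameters go to a numpy ``.npz`` container with a JSON metadata
header (architecture, normalization statistics, training settings).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .network import WindowSegmenterMLP, ModelParams
from .synthetic import ScanProfile, TrialRecord, profile_from_dict

__all__ = ["write_trials", "read_trials", "save_model", "load_model",
           "load_config", "ParseError", "FORMAT_VERSION"]

FORMAT_VERSION = "1"
_COLUMNS = ["time_s", "sensor", "tangential_force", "tumor_label"]


class ParseError(ValueError):
    """A trial container file violates the schema."""


def _flatten(trials) -> List[TrialRecord]:
    if isinstance(trials, dict):
        return [t for ts in trials.values() for t in ts]
    return list(trials)


def write_trials(trials, path: Union[str, Path]) -> None:
    """Write trials (a list or a cohort dict) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in _flatten(trials):
        fname = f"{trial.participant_id}_T{trial.trial_index:03d}.csv"
        t = np.arange(len(trial)) / trial.sampling_rate
        pd.DataFrame({
            "time_s": t,
            "sensor": trial.sensor,
            "tangential_force": trial.tangential_force,
            "tumor_label": trial.tumor_label.astype(int),
        }).to_csv(path / fname, index=False, float_format="%.10g")
        entry = {
            "file": fname,
            "participant_id": trial.participant_id,
            "trial_index": trial.trial_index,
            "tumor_present": bool(trial.tumor_present),
            "sampling_rate": trial.sampling_rate,
        }
        if trial.true_segments is not None:
            entry["true_segments"] = [[int(a), int(b)] for a, b in trial.true_segments]
        if trial.meta:
            entry["meta"] = trial.meta
        entries.append(entry)
    manifest = {"format_version": FORMAT_VERSION, "trials": entries}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_trials(path: Union[str, Path]) -> List[TrialRecord]:
    """Read trials back from a directory written by :func:`write_trials`.

    Entries lacking ``true_segments`` load with segments marked unavailable
    (``None``).
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ParseError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ParseError(f"unknown trial-container format version {version!r}")
    trials = []
    for entry in manifest["trials"]:
        fpath = path / entry["file"]
        df = pd.read_csv(fpath)
        for col in _COLUMNS:
            if col not in df.columns:
                raise ParseError(f"{fpath}: missing column {col!r}")
            if df[col].isna().any():
                raise ParseError(f"{fpath}: column {col!r} has missing values")
        fs = float(entry["sampling_rate"])
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) and not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
            raise ParseError(f"{fpath}: time_s not uniform at 1/{fs} s")
        segments = entry.get("true_segments")
        trials.append(TrialRecord(
            participant_id=entry["participant_id"],
            trial_index=int(entry["trial_index"]),
            tumor_present=bool(entry["tumor_present"]),
            sensor=df["sensor"].to_numpy(),
            tumor_label=df["tumor_label"].to_numpy().astype(np.int8),
            tangential_force=df["tangential_force"].to_numpy(),
            sampling_rate=fs,
            true_segments=[(int(a), int(b)) for a, b in segments] if segments is not None else None,
            meta=entry.get("meta", {}),
        ))
    return trials


def as_cohort(trials: Sequence[TrialRecord]) -> Dict[str, List[TrialRecord]]:
    """Group a flat trial list by participant, preserving trial order."""
    cohort: Dict[str, List[TrialRecord]] = {}
    for t in trials:
        cohort.setdefault(t.participant_id, []).append(t)
    for ts in cohort.values():
        ts.sort(key=lambda t: t.trial_index)
    return cohort


def save_model(model: WindowSegmenterMLP, path: Union[str, Path]) -> None:
    """Serialize a fitted segmenter (weights, biases, metadata) to .npz."""
    meta = {
        "format_version": FORMAT_VERSION,
        "params": model.get_params(deep=False),
        "input_mean": model.input_mean_,
        "input_scale": model.input_scale_,
        "n_features_in": model.n_features_in_,
        "loss_curve": model.loss_curve_,
    }
    meta["params"]["hidden_dims"] = (
        list(model.params_.arch.hidden_dims))
    arrays = {f"W{i + 1}": w for i, w in enumerate(model.params_.weights)}
    arrays.update({f"b{i + 1}": b for i, b in enumerate(model.params_.biases)})
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: Union[str, Path]) -> WindowSegmenterMLP:
    """Load a segmenter saved by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]))
        weights = [data[f"W{i + 1}"] for i in range(4)]
        biases = [data[f"b{i + 1}"] for i in range(4)]
    if meta.get("format_version") != FORMAT_VERSION:
        raise ParseError("unknown model container version")
    params = dict(meta["params"])
    params["hidden_dims"] = tuple(params["hidden_dims"])
    model = WindowSegmenterMLP(**params)
    model.params_ = ModelParams(weights, biases)
    model.input_mean_ = float(meta["input_mean"])
    model.input_scale_ = float(meta["input_scale"])
    model.n_features_in_ = int(meta["n_features_in"])
    model.loss_curve_ = list(meta["loss_curve"])
    return model


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML configuration file (profile / extraction / training)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg


def profile_from_config(cfg: dict) -> ScanProfile:
    return profile_from_dict(cfg.get("profile", {}))
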