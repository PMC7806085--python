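"""Within-participant and across-participant validation protocols.

Two cross-validation designs probe the detector:

* **Within-participant**: a participant's 40 trials are split into 4
  balanced folds of 10. Each fold in turn is the detection-test set
  (dataset #1); the remaining 30 trials are split, randomly and five times,
  into 20 training trials (10 per class, dataset #2-1) and 10
  criterion-calibration trials (5 per class, dataset #2-2).
* **Across-participant**: leave-one-participant-out. The held-out
  participant's 40 trials form dataset #1; from each of the remaining
  participants 26 trials (13 per class) go to training and 14 (7 per class)
  to calibration, re-drawn five times.

Per repetition a network is trained on #2-1 and a criterion calibrated on
#2-2; the five criteria are averaged. Test trials are scored by the
ensemble mean of the five trained networks' score series (configurable to
use only the final network) and judged against the mean criterion; hit and
false-alarm rates over the criterion grid give the fold's ROC and A_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import clone

from .calibration import acc_curve, threshold_criterion
from .detector import trial_score_series, trial_segments
from .network import WindowSegmenterMLP
from .scoring import representative_score, scan_maxima
from .sdt import RocCurve, area_under_curve, roc
from .synthetic import TrialRecord
from .windowing import ExtractionConfig, window_matrices

__all__ = [
    "SplitPlan",
    "FoldResult",
    "ValidationResult",
    "within_participant_plan",
    "across_participant_plan",
    "run_validation",
    "run_within_validation",
    "run_across_validation",
    "compare_with_human",
]

N_REPETITIONS = 5
N_FOLDS = 4


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint trial-id sets for one repetition of one fold."""

    test_ids: Tuple[Hashable, ...]
    train_ids: Tuple[Hashable, ...]
    calib_ids: Tuple[Hashable, ...]
    repetition: int

    def __post_init__(self) -> None:
        a, b, c = map(set, (self.test_ids, self.train_ids, self.calib_ids))
        if a & b or a & c or b & c:
            raise ValueError("test/train/calibration sets must be disjoint")


def _check_balanced(trials: Sequence[TrialRecord], n_expected: int) -> Tuple[List[int], List[int]]:
    present = [i for i, t in enumerate(trials) if t.tumor_present]
    absent = [i for i, t in enumerate(trials) if not t.tumor_present]
    if len(trials) != n_expected or len(present) != n_expected // 2:
        raise ValueError(
            f"protocol requires {n_expected} trials with {n_expected // 2} "
            f"per class; got {len(trials)} with {len(present)} tumor-present"
        )
    return present, absent


def within_participant_plan(
    trials: Sequence[TrialRecord],
    rng: np.random.Generator,
    fold_rng: Optional[np.random.Generator] = None,
) -> List[List[SplitPlan]]:
    """4 balanced folds x 5 random train/calibration splits for one
    participant's 40 trials. ``fold_rng`` (defaults to ``rng``) controls the
    fold partition separately from the repeated #2 splits."""
    present, absent = _check_balanced(trials, 40)
    if fold_rng is None:
        fold_rng = rng
    p = np.array(present)
    a = np.array(absent)
    fold_rng.shuffle(p)
    fold_rng.shuffle(a)
    folds: List[List[SplitPlan]] = []
    for f in range(N_FOLDS):
        test = np.concatenate([p[5 * f:5 * (f + 1)], a[5 * f:5 * (f + 1)]])
        rest_p = np.setdiff1d(p, test)
        rest_a = np.setdiff1d(a, test)
        plans = []
        for rep in range(N_REPETITIONS):
            sp = rng.permutation(rest_p)
            sa = rng.permutation(rest_a)
            plans.append(SplitPlan(
                test_ids=tuple(int(i) for i in test),
                train_ids=tuple(int(i) for i in np.concatenate([sp[:10], sa[:10]])),
                calib_ids=tuple(int(i) for i in np.concatenate([sp[10:15], sa[10:15]])),
                repetition=rep,
            ))
        folds.append(plans)
    return folds


def across_participant_plan(
    cohort: Dict[str, Sequence[TrialRecord]],
    rng: np.random.Generator,
) -> List[Tuple[str, List[SplitPlan]]]:
    """Leave-one-participant-out plans over a cohort.

    Ids are (participant_id, trial_position) pairs. Per held-out
    participant and repetition, every other participant contributes 13
    trials per class to training and 7 per class to calibration.
    """
    per_class: Dict[str, Tuple[List[int], List[int]]] = {}
    for pid, trials in cohort.items():
        per_class[pid] = _check_balanced(trials, 40)
    plans_all: List[Tuple[str, List[SplitPlan]]] = []
    for held_out in cohort:
        test = tuple((held_out, i) for i in range(40))
        plans = []
        for rep in range(N_REPETITIONS):
            train: List[Tuple[str, int]] = []
            calib: List[Tuple[str, int]] = []
            for pid in cohort:
                if pid == held_out:
                    continue
                present, absent = per_class[pid]
                for cls in (present, absent):
                    sel = rng.permutation(np.array(cls))
                    train.extend((pid, int(i)) for i in sel[:13])
                    calib.extend((pid, int(i)) for i in sel[13:20])
            plans.append(SplitPlan(test_ids=test, train_ids=tuple(train),
                                   calib_ids=tuple(calib), repetition=rep))
        plans_all.append((held_out, plans))
    return plans_all


@dataclass
class FoldResult:
    """Outcome of one fold (within) or one held-out participant (across)."""

    fold_id: Hashable
    criteria: List[float]
    c_th_mean: float
    accuracy: float
    n_test: int
    n_correct: int
    roc: RocCurve
    a_g: float
    scores: np.ndarray
    truths: np.ndarray


@dataclass
class ValidationResult:
    """Per-fold results plus mean/SD aggregates."""

    folds: List[FoldResult]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def areas(self) -> np.ndarray:
        return np.array([f.a_g for f in self.folds])

    @property
    def criteria(self) -> np.ndarray:
        return np.array([f.c_th_mean for f in self.folds])

    def summary(self) -> dict:
        return {
            "acc_mean": float(self.accuracies.mean()),
            "acc_sd": float(self.accuracies.std(ddof=1)) if len(self.folds) > 1 else 0.0,
            "a_g_mean": float(self.areas.mean()),
            "a_g_sd": float(self.areas.std(ddof=1)) if len(self.folds) > 1 else 0.0,
            "c_th_mean": float(self.criteria.mean()),
            "c_th_sd": float(self.criteria.std(ddof=1)) if len(self.folds) > 1 else 0.0,
            "n_test": int(sum(f.n_test for f in self.folds)),
            "n_correct": int(sum(f.n_correct for f in self.folds)),
        }


def _score_trials(models, trials, extraction, ensemble, seg_opts):
    scores = []
    for trial in trials:
        used = models if ensemble else models[-1:]
        series = trial_score_series(used, trial, extraction)
        segments = trial_segments(trial, **seg_opts)
        scores.append(representative_score(scan_maxima(series, segments)))
    return np.array(scores)


def run_validation(
    plans: Sequence[Tuple[Hashable, Sequence[SplitPlan]]],
    get_trial,
    segmenter: WindowSegmenterMLP,
    t_window: float = 1.0,
    t_overlap: float = 0.9,
    ensemble: bool = True,
    use_true_segments: bool = False,
    threshold_fraction: float = 0.1,
    min_duration: float = 0.3,
    merge_gap: float = 0.1,
    seed: Optional[int] = None,
) -> ValidationResult:
    """Execute a set of fold plans.

    ``plans`` is a sequence of ``(fold_id, [SplitPlan x 5])``; ``get_trial``
    maps a trial id to its TrialRecord. Per repetition, a clone of
    ``segmenter`` (reseeded deterministically from ``seed``) is trained on
    the repetition's training trials and a criterion calibrated on its
    calibration trials; the five criteria are averaged, the test trials are
    scored by the model ensemble, and accuracy / ROC / A_g are recorded.
    """
    seg_opts = dict(use_true_segments=use_true_segments,
                    threshold_fraction=threshold_fraction,
                    min_duration=min_duration, merge_gap=merge_gap)
    results: List[FoldResult] = []
    for fold_pos, (fold_id, fold_plans) in enumerate(plans):
        models: List[WindowSegmenterMLP] = []
        criteria: List[float] = []
        extraction = None
        for plan in fold_plans:
            train_trials = [get_trial(i) for i in plan.train_ids]
            if extraction is None:
                fs = {t.sampling_rate for t in train_trials}
                if len(fs) != 1:
                    raise ValueError("training trials mix sampling rates")
                extraction = ExtractionConfig(t_window=t_window,
                                              t_overlap=t_overlap,
                                              sampling_rate=fs.pop())
            mats = [window_matrices(t, extraction) for t in train_trials]
            X = np.concatenate([m[0] for m in mats])
            T = np.concatenate([m[1] for m in mats])
            model = clone(segmenter)
            rep_seed = int(np.random.SeedSequence(
                entropy=[0 if seed is None else seed, fold_pos, plan.repetition]
            ).generate_state(1)[0] % (2 ** 31))
            model.set_params(random_state=rep_seed)
            try:
                model.fit(X, T)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"training failed in fold {fold_id!r} repetition "
                    f"{plan.repetition}: {exc}"
                ) from exc
            models.append(model)

            calib_trials = [get_trial(i) for i in plan.calib_ids]
            calib_scores = _score_trials([model], calib_trials, extraction,
                                         ensemble=False, seg_opts=seg_opts)
            calib_truths = np.array([t.tumor_present for t in calib_trials])
            criteria.append(threshold_criterion(
                acc_curve(calib_scores, calib_truths)).c_th)

        c_th_mean = float(np.mean(criteria))
        test_trials = [get_trial(i) for i in fold_plans[0].test_ids]
        scores = _score_trials(models, test_trials, extraction,
                               ensemble=ensemble, seg_opts=seg_opts)
        truths = np.array([t.tumor_present for t in test_trials])
        correct = int(((scores > c_th_mean) == truths).sum())
        curve = roc(scores, truths)
        results.append(FoldResult(
            fold_id=fold_id, criteria=criteria, c_th_mean=c_th_mean,
            accuracy=correct / len(test_trials), n_test=len(test_trials),
            n_correct=correct, roc=curve, a_g=area_under_curve(curve),
            scores=scores, truths=truths,
        ))
    return ValidationResult(folds=results)


def run_within_validation(
    cohort: Dict[str, Sequence[TrialRecord]],
    segmenter: WindowSegmenterMLP,
    seed: Optional[int] = None,
    **kwargs,
) -> Dict[str, ValidationResult]:
    """4-fold within-participant validation, independently per participant."""
    out: Dict[str, ValidationResult] = {}
    for pos, (pid, trials) in enumerate(cohort.items()):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=[0 if seed is None else seed, pos]))
        folds = within_participant_plan(trials, rng)
        plans = [((pid, f), fold_plans) for f, fold_plans in enumerate(folds)]
        out[pid] = run_validation(plans, lambda i: trials[i], segmenter,
                                  seed=seed, **kwargs)
    return out


def run_across_validation(
    cohort: Dict[str, Sequence[TrialRecord]],
    segmenter: WindowSegmenterMLP,
    seed: Optional[int] = None,
    **kwargs,
) -> ValidationResult:
    """Leave-one-participant-out validation over a cohort."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=[0 if seed is None else seed, 12345]))
    plans = across_participant_plan(cohort, rng)
    return run_validation(plans, lambda i: cohort[i[0]][i[1]], segmenter,
                          seed=seed, **kwargs)


def pool_accuracy(result: ValidationResult) -> Tuple[int, int]:
    """Pooled (n_correct, n_test) over all folds, for binomial tests."""
    return (sum(f.n_correct for f in result.folds),
            sum(f.n_test for f in result.folds))


def compare_with_human(model_accuracies: Sequence[float],
                       human_accuracies: Sequence[float]) -> dict:
    """Paired comparison of per-participant accuracies against human data.

    Thin hook over standard routines (Shapiro-Wilk normality check and the
    Wilcoxon signed-rank test); supply per-participant human accuracies from
    an external psychophysical experiment.
    """
    model = np.asarray(model_accuracies, dtype=float)
    human = np.asarray(human_accuracies, dtype=float)
    if model.shape != human.shape:
        raise ValueError("paired accuracy vectors must have equal length")
    diffs = model - human
    shapiro = stats.shapiro(diffs)
    wilcoxon = stats.wilcoxon(model, human)
    return {
        "shapiro_stat": float(shapiro.statistic),
        "shapiro_p": float(shapiro.pvalue),
        "wilcoxon_stat": float(wilcoxon.statistic),
        "wilcoxon_p": float(wilcoxon.pvalue),
    }
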