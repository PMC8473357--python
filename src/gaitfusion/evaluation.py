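"""Online performance metrics and the three experiment designs.

Steady-state recognition is scored sample-wise over steady cycles with the
classification accuracy (CA), and one-vs-rest sensitivity (SE) and
specificity (SP) per mode, macro-averaged:

    CA = 100 * N_true / N_all
    SE_i = 100 * TP / (TP + FN),   SP_i = 100 * TN / (TN + FP)

Prediction is scored per gait transition: a transition counts as correctly
predicted if the online output reaches the upcoming steady mode either
before its actual onset (and holds it until the onset) or at any point in
the following steady segment.  The response time is

    RT = T_pred - T_actual   (ms; negative = predicted before the mode began)

where T_actual is the heel strike starting the steady mode and T_pred the
moment the output first equals it (and, for early predictions, persists
until the onset — a transient flicker does not claim a large negative RT).
PA is the percentage of transitions correctly predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import classifiers as clf
from . import features as feat
from . import preprocessing as prep
from . import segmentation as seg
from .decision import DecisionConfig, DecisionTrace, decide_stream, default_rules
from .modes import N_MODES, LocomotionMode
from .simulate import SimulationConfig, Trial, simulate_trial

__all__ = [
    "EvalReport", "TransitionOutcome", "score_steady", "score_transitions",
    "evaluate_online", "run_window_sweep", "run_modality_comparison",
    "simulate_cohort", "run_lead_recovery_cohort", "PipelineConfig",
]


@dataclass(frozen=True)
class EvalReport:
    """Steady-state recognition metrics, all on a 0-100 scale."""

    ca: float
    se_per_class: np.ndarray     # NaN where a mode has no true samples
    sp_per_class: np.ndarray
    se_mean: float
    sp_mean: float
    n_samples: int


@dataclass(frozen=True)
class TransitionOutcome:
    """Prediction outcome for one gait transition."""

    next_mode: LocomotionMode
    onset_s: float               # T_actual
    predicted: bool
    t_pred_s: float | None
    rt_ms: float | None          # T_pred - T_actual; negative = early


def confusion_counts(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """7x7 confusion matrix (rows = true mode, columns = predicted)."""
    return _sk_confusion(truth, pred, labels=list(range(N_MODES)))


def score_steady(
    output: np.ndarray, truth: np.ndarray, steady_mask: np.ndarray
) -> tuple[np.ndarray, EvalReport]:
    """Sample-wise steady-state scoring of an online output track."""
    output = np.asarray(output)
    truth = np.asarray(truth)
    steady_mask = np.asarray(steady_mask, dtype=bool)
    if not (output.shape == truth.shape == steady_mask.shape):
        raise ValueError("output, truth and steady_mask must have equal length")
    if not steady_mask.any():
        raise ValueError("steady mask selects no samples")
    o = output[steady_mask]
    t = truth[steady_mask]
    counts = confusion_counts(t, o)
    total = counts.sum()
    ca = 100.0 * np.trace(counts) / total
    se = np.full(N_MODES, np.nan)
    sp = np.full(N_MODES, np.nan)
    for i in range(N_MODES):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            se[i] = 100.0 * tp / (tp + fn)
        if tn + fp > 0:
            sp[i] = 100.0 * tn / (tn + fp)
    report = EvalReport(
        ca=float(ca), se_per_class=se, sp_per_class=sp,
        se_mean=float(np.nanmean(se)), sp_mean=float(np.nanmean(sp)),
        n_samples=int(total),
    )
    return counts, report


def score_transitions(
    trace: DecisionTrace,
    transitions: list[seg.Transition],
) -> tuple[float | None, list[TransitionOutcome]]:
    """Per-transition predictive accuracy and response times.

    Returns ``(PA, outcomes)``; PA is None when there are no transitions
    (undefined, not zero).
    """
    if not transitions:
        return None, []
    if trace.times is None:
        raise ValueError("trace must carry sample times for transition scoring")
    t = trace.times
    out = trace.output
    outcomes: list[TransitionOutcome] = []
    for tr in transitions:
        target = int(tr.next_mode)
        i_start = int(np.searchsorted(t, tr.cycle_start_s, side="left"))
        i_actual = int(np.searchsorted(t, tr.onset_s, side="left"))
        i_end = int(np.searchsorted(t, tr.steady_end_s, side="left"))
        # Early prediction: latest run of `target` ending at the onset,
        # clamped to the transition cycle.
        j = i_actual
        while j > i_start and out[j - 1] == target:
            j -= 1
        if j < i_actual:
            t_pred = float(t[j])
            outcomes.append(TransitionOutcome(
                tr.next_mode, tr.onset_s, True, t_pred,
                (t_pred - tr.onset_s) * 1000.0,
            ))
            continue
        # Late recognition within the steady segment.
        late = np.flatnonzero(out[i_actual:i_end] == target)
        if late.size:
            t_pred = float(t[i_actual + late[0]])
            outcomes.append(TransitionOutcome(
                tr.next_mode, tr.onset_s, True, t_pred,
                (t_pred - tr.onset_s) * 1000.0,
            ))
        else:
            outcomes.append(TransitionOutcome(tr.next_mode, tr.onset_s, False, None, None))
    pa = 100.0 * sum(o.predicted for o in outcomes) / len(outcomes)
    return pa, outcomes


# --- End-to-end online evaluation ----------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Operating point of the full pipeline."""

    window_ms: float = 80.0
    agreement_n: int = 100
    train_stride: int = 20        # subsampling of training rows (online step stays 1)
    modality: str = "fusion"      # "emg" | "accel" | "fusion"


def _trial_features(trial: Trial, window_ms: float) -> feat.FeatureMatrix:
    return feat.build_features(prep.preprocess_trial(trial), window_ms)


def _trial_cycles(trial: Trial) -> list[seg.GaitCycle]:
    hs = seg.detect_heel_strikes(trial.markers[0], trial.markers[2], trial.fs)
    return seg.segment_cycles(hs, trial.truth_labels, trial.fs)


def _training_rows(
    fm: feat.FeatureMatrix, cycles: list[seg.GaitCycle], trial: Trial, stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state rows only, subsampled by `stride`."""
    ends = np.round(fm.t * trial.fs).astype(int)
    mask = seg.steady_sample_mask(cycles, trial.n_samples, trial.fs)[ends]
    rows = np.flatnonzero(mask)[::stride]
    return fm.X[rows], fm.y[rows]


def evaluate_online(
    train_trials: list[Trial],
    test_trials: list[Trial],
    spec: clf.ClassifierSpec,
    pipeline: PipelineConfig = PipelineConfig(),
    feature_cache: dict | None = None,
) -> dict:
    """Train on steady-state rows of the training trials, then score the
    held-out trials sample-by-sample through the vote + legality layer.

    Normalisation bounds and hyperparameters are learned on training trials
    only.  Returns pooled steady-state metrics, per-transition outcomes and
    the decision traces.
    """
    cols = feat.modality_columns(pipeline.modality)

    def fm_of(trial: Trial) -> feat.FeatureMatrix:
        if feature_cache is None:
            return _trial_features(trial, pipeline.window_ms)
        key = (id(trial), pipeline.window_ms)
        if key not in feature_cache:
            feature_cache[key] = _trial_features(trial, pipeline.window_ms)
        return feature_cache[key]

    X_parts, y_parts = [], []
    for trial in train_trials:
        fm = fm_of(trial).subset(cols)
        X, y = _training_rows(fm, _trial_cycles(trial), trial, pipeline.train_stride)
        X_parts.append(X)
        y_parts.append(y)
    X_train = np.vstack(X_parts)
    y_train = np.concatenate(y_parts)
    bounds = feat.fit_norm_bounds(X_train)
    model = clf.tune_and_train(feat.apply_norm(X_train, bounds), y_train, spec)

    truth_all, out_all, steady_all = [], [], []
    outcomes: list[TransitionOutcome] = []
    traces: list[DecisionTrace] = []
    for trial in test_trials:
        fm = fm_of(trial).subset(cols)
        raw = clf.predict_stream(model, feat.apply_norm(fm.X, bounds))
        dec_cfg = DecisionConfig(
            agreement_n=pipeline.agreement_n,
            initial_mode=LocomotionMode(int(trial.truth_labels[0])),
        )
        trace = decide_stream(raw, dec_cfg, default_rules(), times=fm.t)
        cycles = _trial_cycles(trial)
        ends = np.round(fm.t * trial.fs).astype(int)
        steady = seg.steady_sample_mask(cycles, trial.n_samples, trial.fs)[ends]
        truth_all.append(fm.y)
        out_all.append(trace.output)
        steady_all.append(steady)
        _, tr_outcomes = score_transitions(trace, seg.transitions_from_cycles(cycles))
        outcomes.extend(tr_outcomes)
        traces.append(trace)

    counts, report = score_steady(
        np.concatenate(out_all), np.concatenate(truth_all), np.concatenate(steady_all)
    )
    rts = [o.rt_ms for o in outcomes if o.predicted]
    pa = 100.0 * sum(o.predicted for o in outcomes) / len(outcomes) if outcomes else None
    return {
        "model": model,
        "confusion": counts,
        "report": report,
        "ca": report.ca,
        "se_mean": report.se_mean,
        "sp_mean": report.sp_mean,
        "pa": pa,
        "mean_rt_ms": float(np.mean(rts)) if rts else None,
        "outcomes": outcomes,
        "traces": traces,
    }


def simulate_cohort(
    task: int, n_trials: int, seed: int, **config_overrides
) -> list[Trial]:
    """Simulate a cohort of trials of one task with distinct sub-seeds."""
    base = SimulationConfig.for_task(task, **config_overrides)
    return [simulate_trial(replace(base, seed=seed * 10_000 + k)) for k in range(n_trials)]


#: Coarse RBF grid used for cohort-scale runs (full grid in classifiers).
COHORT_SVM_PARAMS = {"c_grid": [1.0, 16.0, 256.0],
                     "g_grid": [2.0 ** -5, 2.0 ** -2, 2.0]}


def run_lead_recovery_cohort(
    seeds: list[int],
    tasks: list[int] = [1, 2, 3, 4, 5],
    n_trials: int = 6,
    method: str = "SVM",
    pipeline: PipelineConfig = PipelineConfig(train_stride=100),
    modalities: tuple[str, ...] = ("emg", "accel", "fusion"),
    **config_overrides,
) -> dict:
    """The end-to-end activation-lead experiment over a simulated cohort.

    For every (seed, task) cell a cohort of trials is simulated, split into
    training and held-out trials, and the online pipeline is evaluated per
    data modality.  Returns, per modality, the steady-state metrics pooled
    over all held-out samples and the prediction metrics pooled over all
    gait transitions.
    """
    agg = {m: {"true": 0, "all": 0, "outcomes": []} for m in modalities}
    for seed in seeds:
        for task in tasks:
            trials = simulate_cohort(task, n_trials, seed, **config_overrides)
            train, test = clf.split_trials(trials, seed=seed)
            cache: dict = {}
            for m in modalities:
                spec = clf.ClassifierSpec(
                    method=method, seed=seed,
                    params=COHORT_SVM_PARAMS if method == "SVM" else {},
                )
                res = evaluate_online(train, test, spec,
                                      replace(pipeline, modality=m), cache)
                a = agg[m]
                a["true"] += int(np.trace(res["confusion"]))
                a["all"] += int(res["report"].n_samples)
                a["outcomes"].extend(res["outcomes"])
    out: dict = {}
    for m in modalities:
        a = agg[m]
        rts = [o.rt_ms for o in a["outcomes"] if o.predicted]
        out[m] = {
            "ca_pct": 100.0 * a["true"] / a["all"],
            "n_steady": a["all"],
            "pa_pct": (100.0 * sum(o.predicted for o in a["outcomes"])
                       / len(a["outcomes"])) if a["outcomes"] else None,
            "mean_rt_ms": float(np.mean(rts)) if rts else None,
            "n_transitions": len(a["outcomes"]),
        }
    return out


def run_window_sweep(
    trials: list[Trial],
    spec: clf.ClassifierSpec,
    windows_ms: list[float],
    pipeline: PipelineConfig = PipelineConfig(),
    split_seed: int = 0,
) -> pd.DataFrame:
    """Full pipeline per window size on an identical trial split."""
    if not windows_ms:
        raise ValueError("need at least one window size")
    train, test = clf.split_trials(trials, seed=split_seed)
    rows = []
    for w in windows_ms:
        res = evaluate_online(train, test, spec, replace(pipeline, window_ms=float(w)))
        rows.append({"window_ms": float(w), "ca": res["ca"], "pa": res["pa"],
                     "mean_rt_ms": res["mean_rt_ms"]})
    return pd.DataFrame(rows)


def run_modality_comparison(
    trials: list[Trial],
    spec: clf.ClassifierSpec,
    pipeline: PipelineConfig = PipelineConfig(),
    modalities: tuple[str, ...] = ("emg", "accel", "fusion"),
    split_seed: int = 0,
) -> pd.DataFrame:
    """Identical protocol per data type; column subsetting happens before
    normalisation fitting so no cross-modality leakage occurs."""
    train, test = clf.split_trials(trials, seed=split_seed)
    cache: dict = {}
    rows = []
    for m in modalities:
        res = evaluate_online(train, test, spec, replace(pipeline, modality=m),
                              feature_cache=cache)
        rows.append({"modality": m, "n_columns": feat.modality_columns(m).size,
                     "ca": res["ca"], "se_mean": res["se_mean"], "pa": res["pa"],
                     "mean_rt_ms": res["mean_rt_ms"]})
    return pd.DataFrame(rows)
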