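"""Pseudo-online movement detection from sliding-window coherence.

Replays epoched trials through the causal windowing logic of an online
system: 1-s windows advanced by a shift of 125, 250 or 500 ms, each carrying
its END time as timestamp. Two detectors are evaluated:

* CMC onset (double threshold): the 95th percentile of all rest-trial window
  coherences is the statistical threshold; the CMC onset of a task trial is
  the end time of the first window of the earliest run of consecutive
  supra-threshold windows spanning ≥ 500 ms of new data
  (k = ceil(500 ms / shift) windows: 4 at 125 ms, 2 at 250 ms, 1 at 500 ms).
  Versus the EMG onset this gives TD (delayed = true), FD (anticipated =
  false) or ND (none) per trial, plus the mean delay MD over TD trials.
* Leave-one-out classification: one linear SVM per task trial, trained on
  every other trial's whole-interval features and applied per window of the
  held-out trial. With accumulation factor M, the trial is FP if M
  consecutive task predictions fall entirely before the EMG onset, else TP
  if M consecutive task predictions occur after it (T_M = end time of the
  M-th window), else FN. Aggregates: hit rate = TP/N, FPR = FP/N,
  FNR = FN/N (N task trials; the three always sum to 1) and MD = mean of
  T_M − EMG onset over TP trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cmcdetect.cmc import single_trial_cmc
from cmcdetect.features import FeatureMatrix
from cmcdetect.offline_eval import make_classifier
from cmcdetect.preprocess import TrialSet

__all__ = [
    "SlidingWindowConfig",
    "CMCTrajectory",
    "PseudoOnlineResult",
    "sliding_windows",
    "cmc_trajectory",
    "rest_threshold",
    "required_run_length",
    "cmc_onset",
    "compare_onsets",
    "detection_summary",
    "score_prediction_string",
    "classify_trials_loo",
    "metric_table",
]

PERSISTENCE_S = 0.5  # supra-threshold span required for a CMC onset


@dataclass
class SlidingWindowConfig:
    """1-s analysis windows advanced by ``shift`` seconds; timestamps are END times."""

    shift: float = 0.125
    window_len: float = 1.0

    def __post_init__(self) -> None:
        if self.shift <= 0 or self.window_len <= 0:
            raise ValueError("window_len and shift must be positive")


def sliding_windows(n_samples: int, fs: float,
                    cfg: SlidingWindowConfig | None = None,
                    ) -> list[tuple[int, int, float]]:
    """Half-open sample windows ``[start, start+W)`` with their end times.

    For an epoch of duration T the count is ``floor((T − W)/shift) + 1``
    (57 windows for an 8-s trial at 125 ms shift). Raises if the epoch is
    shorter than one window.
    """
    cfg = cfg or SlidingWindowConfig()
    w = int(round(cfg.window_len * fs))
    step = int(round(cfg.shift * fs))
    if n_samples < w:
        raise ValueError("epoch shorter than the analysis window")
    out = []
    for s in range(0, n_samples - w + 1, step):
        out.append((s, s + w, (s + w) / fs))
    return out


@dataclass
class CMCTrajectory:
    """Windowed coherence series of one trial for one pair."""

    trial: int
    pair: tuple[str, str]
    end_times: np.ndarray  # s from cue (window END times)
    values: np.ndarray  # coherence at f0, in [0, 1]
    shift: float


def cmc_trajectory(trial, pair: tuple[str, str], f0: float, trials: TrialSet,
                   cfg: SlidingWindowConfig | None = None) -> CMCTrajectory:
    """Single-trial CMC per sliding window of one epoched trial."""
    cfg = cfg or SlidingWindowConfig()
    ci = trials.channel_labels.index(pair[0])
    mi = trials.muscle_labels.index(pair[1])
    wins = sliding_windows(trial.eeg.shape[1], trials.fs, cfg)
    vals, times = [], []
    for s0, s1, t_end in wins:
        vals.append(single_trial_cmc(trial.eeg[ci, s0:s1],
                                     trial.emg[mi, s0:s1], trials.fs,
                                     f0, pair=pair).value)
        times.append(t_end)
    return CMCTrajectory(trial.index, pair, np.array(times), np.array(vals),
                         cfg.shift)


def rest_threshold(rest_trajectories: list[CMCTrajectory],
                   percentile: float = 95.0) -> float:
    """Statistical threshold: percentile of all pooled rest-trial CMC values.

    Uses the linear-interpolation percentile definition.
    """
    if not rest_trajectories:
        raise ValueError("need at least one rest trajectory")
    pool = np.concatenate([t.values for t in rest_trajectories])
    if pool.size == 0:
        raise ValueError("empty rest CMC pool")
    return float(np.percentile(pool, percentile))


def required_run_length(shift: float,
                        persistence: float = PERSISTENCE_S) -> int:
    """Windows needed for a supra-threshold run to span the persistence time.

    Each window contributes ``shift`` seconds of new data, so
    k = ceil(persistence / shift): 4 at 125 ms, 2 at 250 ms, 1 at 500 ms.
    """
    return max(1, math.ceil(persistence / shift - 1e-9))


def cmc_onset(traj: CMCTrajectory, threshold: float) -> float | None:
    """CMC onset: end time of the first window of the earliest qualifying run.

    A run qualifies when at least ``required_run_length(shift)`` consecutive
    windows exceed the threshold. Returns ``None`` if no run qualifies.
    """
    supra = traj.values > threshold
    k = required_run_length(traj.shift)
    run = 0
    for i, s in enumerate(supra):
        run = run + 1 if s else 0
        if run >= k:
            return float(traj.end_times[i - k + 1])
    return None


def compare_onsets(cmc_onset_s: float | None, emg_onset_s: float) -> str:
    """Classify a detection: 'TD' (delayed/true), 'FD' (anticipated), 'ND' (missed).

    Exact coincidence counts as TD (the detection is not anticipated).
    """
    if cmc_onset_s is None:
        return "ND"
    return "TD" if cmc_onset_s >= emg_onset_s else "FD"


def detection_summary(categories: list[str],
                      delays: list[float]) -> dict[str, float | None]:
    """TD/FD/ND rates (normalized by task-trial count) and mean delay over TD trials."""
    if not categories:
        raise ValueError("need at least one task trial")
    n = len(categories)
    td = [d for c, d in zip(categories, delays) if c == "TD"]
    return {
        "td_rate": categories.count("TD") / n,
        "fd_rate": categories.count("FD") / n,
        "nd_rate": categories.count("ND") / n,
        "md": float(np.mean(td)) if td else None,
        "n_trials": n,
    }


def score_prediction_string(preds: np.ndarray, end_times: np.ndarray,
                            emg_onset_s: float, m: int
                            ) -> tuple[str, float | None]:
    """Assign TP/FP/FN to one trial's window predictions under accumulation M.

    A window is *after* the onset when its end time exceeds the EMG onset;
    runs straddling the onset are split at that boundary. The trial is FP if
    any M consecutive task-predicted windows lie entirely before the onset
    (pre-onset detections take precedence: the detector would have fired
    early), else TP if M consecutive task predictions occur after it —
    ``T_M`` is the end time of the M-th window of the first such run — else
    FN. Returns ``(outcome, T_M)`` with ``T_M`` set only for TP.
    """
    if m < 1:
        raise ValueError("accumulation factor M must be >= 1")
    preds = np.asarray(preds, bool)
    end_times = np.asarray(end_times, float)
    after = end_times > emg_onset_s
    run = 0
    for p, a in zip(preds, after):
        if p and not a:
            run += 1
            if run >= m:
                return "FP", None
        else:
            run = 0
    run = 0
    for p, a, t in zip(preds, after, end_times):
        if p and a:
            run += 1
            if run == m:
                return "TP", float(t)
        else:
            run = 0
    return "FN", None


@dataclass
class PseudoOnlineResult:
    """Leave-one-out pseudo-online classification outcome for one session/condition."""

    shift: float
    m: int
    outcomes: dict[int, str] = field(default_factory=dict)  # trial -> TP|FP|FN
    t_m: dict[int, float] = field(default_factory=dict)  # trial -> detection time
    delays: dict[int, float] = field(default_factory=dict)  # trial -> T_M − onset
    predictions: dict[int, np.ndarray] = field(default_factory=dict)
    n_task_trials: int = 0

    @property
    def hit_rate(self) -> float:
        return self._rate("TP")

    @property
    def fpr(self) -> float:
        return self._rate("FP")

    @property
    def fnr(self) -> float:
        return self._rate("FN")

    @property
    def mean_delay(self) -> float | None:
        return float(np.mean(list(self.delays.values()))) if self.delays \
            else None

    def _rate(self, kind: str) -> float:
        vals = list(self.outcomes.values())
        return vals.count(kind) / self.n_task_trials if vals else float("nan")

    def summary(self) -> dict[str, float | None]:
        return {"shift": self.shift, "M": self.m, "hit_rate": self.hit_rate,
                "fpr": self.fpr, "fnr": self.fnr, "md": self.mean_delay,
                "n_trials": self.n_task_trials}


def classify_trials_loo(fm: FeatureMatrix,
                        window_features: dict[int, np.ndarray],
                        window_times: dict[int, np.ndarray],
                        emg_onsets: dict[int, float],
                        m: int, shift: float) -> PseudoOnlineResult:
    """Leave-one-task-trial-out pseudo-online classification.

    ``fm`` holds whole-interval training features (one observation per kept
    trial, both conditions); ``window_features[t]`` the (n_windows × n_pairs)
    sliding-window features of task trial ``t`` and ``window_times[t]`` the
    matching window end times. For each task trial with an EMG onset, a
    linear SVM is trained on all *other* observations (rest trials included —
    a binary classifier needs both classes) and applied per window; the
    prediction string is scored by :func:`score_prediction_string`. Task
    trials without an EMG onset are excluded with a warning.
    """
    res = PseudoOnlineResult(shift=shift, m=m)
    task_trials = fm.trial_indices[fm.y]
    for t in task_trials:
        t = int(t)
        if t not in window_features:
            continue
        if t not in emg_onsets or emg_onsets[t] is None:
            warnings.warn(f"task trial {t} has no EMG onset; excluded")
            continue
        train = fm.trial_indices != t
        clf = make_classifier()
        clf.fit(fm.X[train], fm.y[train])
        preds = clf.predict(window_features[t]).astype(bool)
        outcome, t_m = score_prediction_string(preds, window_times[t],
                                               emg_onsets[t], m)
        res.outcomes[t] = outcome
        res.predictions[t] = preds
        if outcome == "TP":
            res.t_m[t] = t_m
            res.delays[t] = t_m - emg_onsets[t]
        res.n_task_trials += 1
    return res


def metric_table(results: list[dict]) -> pd.DataFrame:
    """Long-format performance table with mean ± SE across sessions.

    ``results`` holds one dict per (session, movement, side, shift, M) with
    keys movement, side, shift, M, hit_rate, fpr, fnr, md, n_trials. Rows
    are aggregated over sessions; the SE columns are 0 for a single session.
    """
    df = pd.DataFrame(results)
    if df.empty:
        raise ValueError("no results to tabulate")
    grouped = df.groupby(["movement", "side", "shift", "M"], dropna=False)
    rows = []
    for key, g in grouped:
        row = dict(zip(["movement", "side", "shift", "M"], key))
        for col in ("hit_rate", "fpr", "fnr", "md"):
            vals = g[col].dropna().to_numpy(float)
            row[col] = vals.mean() if vals.size else np.nan
            row[f"{col}_se"] = (vals.std(ddof=1) / np.sqrt(vals.size)
                                if vals.size > 1 else 0.0)
        row["n_trials"] = int(g["n_trials"].sum())
        row["n_sessions"] = len(g)
        rows.append(row)
    return pd.DataFrame(rows)
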