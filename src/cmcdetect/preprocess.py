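"""Filtering, epoching, channel subsetting and trial screening.

EEG is band-pass filtered 3–60 Hz with a 50 Hz notch; EMG is anti-alias
filtered, downsampled from 2 kHz to 1 kHz, high-pass filtered at 3 Hz and
notched at 50 Hz. All filters are applied forward-backward (zero phase) so
that no group delay shifts onset timing. Task trials are segmented in 8-s
epochs from the cue, rest trials in 4-s epochs, and the EEG is restricted to
the 28-channel sensorimotor subset.

Screening applies three rules per trial:

* EEG amplitude: samples exceeding 100 µV in absolute value mark a channel
  artifactual; more than one artifactual channel rejects the trial, exactly
  one is repaired by spherical-spline interpolation from the remaining
  channels.
* EMG statistics: a per-trial characteristic vector (RMS, kurtosis, 95%
  spectral edge frequency, zero-crossing rate) is compared to the per-
  condition median; any component deviating by more than k robust MADs flags
  the trial for review (auto-rejected in batch mode).
* Compliance: rest trials showing sustained supra-baseline target-muscle
  activity, and task trials never exceeding baseline during the movement
  period, are rejected as non-compliant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.special import eval_legendre
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import median_abs_deviation

from cmcdetect.session import Session

__all__ = [
    "SENSORIMOTOR_CHANNELS",
    "Trial",
    "TrialSet",
    "filter_eeg",
    "filter_emg",
    "epoch",
    "screen_eeg_artifacts",
    "screen_emg_artifacts",
    "screen_compliance",
    "spherical_spline_interpolate",
]

#: 28 channels over the sensorimotor strip (extended 10-20 montage).
SENSORIMOTOR_CHANNELS = [
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
]

KEPT = "kept"
REJECTED_ARTIFACT = "rejected_artifact"
REJECTED_NONCOMPLIANT = "rejected_noncompliant"


def filter_eeg(raw: np.ndarray, fs: float, band: tuple[float, float] = (3.0, 60.0),
               notch: float = 50.0, order: int = 4, q: float = 30.0) -> np.ndarray:
    """Zero-phase band-pass (default 3–60 Hz) plus 50 Hz notch on continuous EEG.

    ``raw`` is (channels, samples) or (samples,). Requires ``fs`` comfortably
    above twice the upper band edge.
    """
    if fs < max(200.0, 2.5 * band[1]):
        raise ValueError(f"sampling rate {fs} Hz too low for band edge "
                         f"{band[1]} Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, raw, axis=-1)
    if notch:
        b, a = signal.iirnotch(notch, q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def filter_emg(raw: np.ndarray, fs_in: float = 2000.0,
               fs_out: float = 1000.0, hp: float = 3.0,
               notch: float = 50.0) -> np.ndarray:
    """Anti-alias, decimate to 1 kHz, 3 Hz high-pass and 50 Hz notch the EMG.

    The nominal 3–500 Hz band-pass is realized as an 8th-order anti-alias
    low-pass at 400 Hz applied *before* decimation (a 500 Hz edge is not
    realizable at the 1 kHz output Nyquist), followed by the high-pass and
    notch at the output rate. Output length is ``input length / ratio``.
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(f"decimation ratio {ratio} must be a positive integer")
    ratio = int(round(ratio))
    out = np.asarray(raw, float)
    if ratio > 1:
        sos = signal.butter(8, 0.4 * fs_out, btype="lowpass", fs=fs_in,
                            output="sos")  # 400 Hz anti-alias for 1 kHz output
        out = signal.sosfiltfilt(sos, out, axis=-1)
        out = out[..., ::ratio]
    sos = signal.butter(4, hp, btype="highpass", fs=fs_out, output="sos")
    out = signal.sosfiltfilt(sos, out, axis=-1)
    if notch:
        b, a = signal.iirnotch(notch, 30.0, fs=fs_out)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


@dataclass
class Trial:
    """One epoched trial with its screening status."""

    index: int
    label: str  # 'task' | 'rest'
    eeg: np.ndarray  # (n_channels, n_samples) at the common rate
    emg: np.ndarray  # (n_muscles, n_samples)
    status: str = KEPT
    reason: str | None = None
    interpolated_channels: list[str] = field(default_factory=list)


@dataclass
class TrialSet:
    """Epoched task/rest trials plus bookkeeping shared across stages."""

    trials: list[Trial]
    fs: float
    channel_labels: list[str]
    muscle_labels: list[str]
    mvc: dict[str, float] = field(default_factory=dict)
    truth: object | None = None  # SessionTruth passthrough for synthetic data

    def kept(self, label: str | None = None) -> list[Trial]:
        return [t for t in self.trials
                if t.status == KEPT and (label is None or t.label == label)]

    def counts(self) -> dict[str, int]:
        out = {KEPT: 0, REJECTED_ARTIFACT: 0, REJECTED_NONCOMPLIANT: 0}
        for t in self.trials:
            out[t.status] += 1
        return out


def epoch(session: Session, subset: list[str] | None = None,
          task_dur: float = 8.0, rest_dur: float = 4.0,
          prefiltered: bool = False) -> TrialSet:
    """Filter the continuous signals and cut cue-locked epochs.

    EEG is restricted to ``subset`` (default: the 28 sensorimotor channels);
    EMG keeps all muscles and is resampled to the EEG rate. Epochs start at
    the cue sample (half-open ``[cue, cue + duration)``, 0-based indices).
    Set ``prefiltered=True`` to skip filtering (already-conditioned input).
    """
    subset = SENSORIMOTOR_CHANNELS if subset is None else subset
    if not subset:
        raise ValueError("channel subset must not be empty")
    missing = [c for c in subset if c not in session.channel_labels]
    if missing:
        raise ValueError(f"channels not in session: {missing}")
    rows = [session.channel_labels.index(c) for c in subset]

    eeg = session.eeg[rows]
    emg = session.emg
    if not prefiltered:
        eeg = filter_eeg(eeg, session.fs_eeg)
        emg = filter_emg(emg, session.fs_emg, fs_out=session.fs_eeg)
    fs = session.fs_eeg

    trials = []
    n_total = eeg.shape[1]
    for i, (lab, cue) in enumerate(zip(session.trial_labels,
                                       session.cue_times)):
        dur = task_dur if lab == "task" else rest_dur
        s0 = int(round(cue * fs))
        s1 = s0 + int(round(dur * fs))
        if s1 > n_total:
            raise ValueError(f"trial {i}: cue at {cue:.3f} s extends past "
                             "the end of the recording")
        trials.append(Trial(i, lab, eeg[:, s0:s1].copy(), emg[:, s0:s1].copy()))
    return TrialSet(trials, fs, list(subset), list(session.muscle_labels),
                    dict(session.mvc), session.truth)


# ---------------------------------------------------------------------------
# spherical-spline channel interpolation (Perrin et al. scalp splines)

def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spline kernel g(cosθ) = Σ (2n+1)/(nᵐ(n+1)ᵐ)·Pₙ(cosθ) / 4π."""
    out = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * eval_legendre(n, cosang)
    return out / (4 * np.pi)


@lru_cache(maxsize=8)
def _montage_positions_cached(labels: tuple[str, ...]) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    out = []
    for lab in labels:
        if lab not in pos:
            raise ValueError(f"no montage position for channel {lab!r}")
        p = np.asarray(pos[lab], float)
        out.append(p / np.linalg.norm(p))
    return np.array(out)


def _montage_positions(labels: list[str]) -> np.ndarray:
    """Unit-sphere positions of 10-20 labels from the standard montage."""
    return _montage_positions_cached(tuple(labels))


def spherical_spline_interpolate(data: np.ndarray, labels: list[str],
                                 bad: str, m: int = 4,
                                 reg: float = 1e-5) -> np.ndarray:
    """Reconstruct one channel from the others by spherical-spline interpolation.

    ``data`` is (channels, samples) in the order of ``labels``. Returns the
    interpolated time series for the bad channel (stiffness ``m`` = 4,
    Tikhonov regularization ``reg`` on the spline system diagonal).
    """
    pos = _montage_positions(labels)
    bi = labels.index(bad)
    good = [i for i in range(len(labels)) if i != bi]
    pg = pos[good]
    cos_gg = np.clip(pg @ pg.T, -1.0, 1.0)
    cos_bg = np.clip(pos[bi] @ pg.T, -1.0, 1.0)
    G = _g_matrix(cos_gg, m) + reg * np.eye(len(good))
    # spline system with a constant term; weights solve [[G,1],[1ᵀ,0]]
    n = len(good)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.zeros((n + 1, data.shape[1]))
    rhs[:n] = data[good]
    sol = np.linalg.solve(A, rhs)
    gb = _g_matrix(cos_bg, m)
    return gb @ sol[:n] + sol[n]


def screen_eeg_artifacts(trials: TrialSet,
                         threshold_uv: float = 100.0) -> TrialSet:
    """Apply the 100 µV rule: reject multi-channel artifacts, repair single ones.

    Channels whose absolute amplitude exceeds ``threshold_uv`` anywhere in a
    trial are artifactual. Trials with more than one such channel are marked
    ``rejected_artifact``; trials with exactly one get that channel replaced
    by spherical-spline interpolation from the remaining subset channels, and
    the (trial, channel) pair is logged. Operates in place and returns the set.
    """
    for tr in trials.trials:
        if tr.status != KEPT:
            continue
        bad = np.flatnonzero(np.abs(tr.eeg).max(axis=1) > threshold_uv)
        if bad.size > 1:
            tr.status = REJECTED_ARTIFACT
            tr.reason = "eeg_amplitude:" + ",".join(
                trials.channel_labels[b] for b in bad)
        elif bad.size == 1:
            lab = trials.channel_labels[int(bad[0])]
            tr.eeg[int(bad[0])] = spherical_spline_interpolate(
                tr.eeg, trials.channel_labels, lab)
            tr.interpolated_channels.append(lab)
    return trials


def _emg_characteristics(x: np.ndarray, fs: float) -> np.ndarray:
    """Per-trial EMG characteristic vector: RMS, kurtosis, SEF95, ZCR."""
    rms = float(np.sqrt(np.mean(x**2)))
    kurt = float(_kurtosis(x))
    f, p = signal.periodogram(x, fs=fs)
    c = np.cumsum(p)
    sef = float(f[np.searchsorted(c, 0.95 * c[-1])]) if c[-1] > 0 else 0.0
    zcr = float(np.mean(np.abs(np.diff(np.signbit(x).astype(int)))))
    return np.array([rms, kurt, sef, zcr])


def screen_emg_artifacts(trials: TrialSet, target_muscle: str,
                         k: float = 4.5, auto_reject: bool = True
                         ) -> tuple[TrialSet, list[tuple[int, str]]]:
    """Flag trials whose target-muscle EMG statistics deviate from the condition median.

    Separately for task and rest trials, a characteristic vector (RMS,
    kurtosis, 95% spectral edge frequency, zero-crossing rate) is computed
    per trial and compared to the condition median; a trial whose vector
    deviates by more than ``k`` scaled MADs in any component is flagged. In
    batch mode (``auto_reject=True``) flagged trials are rejected; otherwise
    only the review list is returned for interactive confirmation.
    """
    mi = trials.muscle_labels.index(target_muscle)
    review: list[tuple[int, str]] = []
    for label in ("task", "rest"):
        cond = [t for t in trials.trials if t.status == KEPT and
                t.label == label]
        if len(cond) < 3:
            warnings.warn(f"<3 kept {label} trials: EMG statistical screening "
                          "skipped (median unstable)")
            continue
        feats = np.array([_emg_characteristics(t.emg[mi], trials.fs)
                          for t in cond])
        med = np.median(feats, axis=0)
        mad = median_abs_deviation(feats, axis=0, scale="normal")
        mad = np.maximum(mad, 1e-3 * np.maximum(np.abs(med), 1e-12))
        for t, f in zip(cond, feats):
            dev = np.abs(f - med) / mad
            if np.any(dev > k):
                names = ["rms", "kurtosis", "sef95", "zcr"]
                why = ",".join(n for n, d in zip(names, dev) if d > k)
                review.append((t.index, why))
                if auto_reject:
                    t.status = REJECTED_ARTIFACT
                    t.reason = f"emg_statistical:{why}"
    return trials, review


def screen_compliance(trials: TrialSet, target_muscle: str,
                      prep_dur: float = 4.0, k: float = 5.0,
                      sustain: float = 0.5) -> TrialSet:
    """Reject non-compliant trials from the target-muscle envelope.

    The baseline distribution pools the target-muscle envelopes of all kept
    rest trials; its median + ``k``·MAD is the activity threshold. Rest
    trials exceeding it continuously for at least ``sustain`` seconds are
    rejected (participant moved); task trials that never exceed it during the
    movement period ``[prep_dur, end)`` are rejected (instruction missed).
    """
    from cmcdetect.emg_onset import emg_envelope

    mi = trials.muscle_labels.index(target_muscle)
    rest = [t for t in trials.trials if t.status == KEPT and t.label == "rest"]
    if not rest:
        return trials
    envs = {t.index: emg_envelope(t.emg[mi], trials.fs)
            for t in trials.trials if t.status == KEPT}
    pool = np.concatenate([envs[t.index] for t in rest])
    thr = np.median(pool) + k * median_abs_deviation(pool, scale="normal")
    n_sustain = int(round(sustain * trials.fs))
    for t in trials.trials:
        if t.status != KEPT:
            continue
        env = envs[t.index]
        if t.label == "rest":
            above = env > thr
            if _longest_run(above) >= n_sustain:
                t.status = REJECTED_NONCOMPLIANT
                t.reason = "movement_during_rest"
        else:
            move = env[int(round(prep_dur * trials.fs)):]
            if not np.any(move > thr):
                t.status = REJECTED_NONCOMPLIANT
                t.reason = "no_movement_during_task"
    return trials


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best
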