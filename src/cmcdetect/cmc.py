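"""Cortico-muscular coherence estimation.

Magnitude-squared coherence (MSC) between EEG and *rectified* EMG:

    C(f) = |Σₖ Xₖ(f)·conj(Yₖ(f))|² / (Σₖ|Xₖ(f)|² · Σₖ|Yₖ(f)|²)

over Hann-tapered, mean-detrended segments k. Two estimators are built on
it:

* across-trial coherence — each 8-s task epoch contributes eight
  non-overlapping 1-s segments pooled across trials (1 Hz resolution); the
  beta-band argmax defines the characteristic frequency f0 of a pair;
* single-trial/windowed coherence — Welch estimate inside a 1-s window from
  seven half-overlapped 250-ms Hann segments (4 Hz resolution), evaluated at
  the grid frequency nearest f0.

The estimator is biased upward for few segments: independent signals give
E[C] ≈ 1/L for L segments. No bias correction is applied; the floor is
documented and used as the reference level in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "CoherenceSpectrum",
    "SingleTrialCMC",
    "msc",
    "segment_epoch",
    "across_trial_cmc",
    "characteristic_frequency",
    "single_trial_cmc",
]


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence over frequency for one EEG–EMG pair."""

    freqs: np.ndarray  # Hz
    coh: np.ndarray  # in [0, 1]
    n_segments: int
    pair: tuple[str, str] | None = None


@dataclass
class SingleTrialCMC:
    """Coherence of one window/trial at (the bin nearest) the characteristic frequency."""

    value: float
    freq_evaluated: float  # actual grid frequency used
    f0: float  # requested characteristic frequency
    pair: tuple[str, str] | None = None


def msc(x_segments: np.ndarray, y_segments: np.ndarray, fs: float,
        fmax: float = 60.0, detrend: bool = True,
        pair: tuple[str, str] | None = None) -> CoherenceSpectrum:
    """Magnitude-squared coherence from paired signal segments.

    ``x_segments`` and ``y_segments`` are (n_segments, segment_length); for
    cortico-muscular use, y is the rectified EMG. Segments are mean-detrended
    and Hann-tapered before the FFT; the spectrum is restricted to
    [0, ``fmax``] Hz. At least two segments are required (a single segment
    gives coherence identically 1, which carries no information).
    """
    x = np.asarray(x_segments, float)
    y = np.asarray(y_segments, float)
    if x.ndim != 2 or x.shape != y.shape:
        raise ValueError("need matching (n_segments, length) arrays")
    if x.shape[0] < 2:
        raise ValueError("coherence needs at least 2 segments")
    if detrend:
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean(axis=1, keepdims=True)
    taper = signal.windows.hann(x.shape[1], sym=False)
    X = np.fft.rfft(x * taper, axis=1)
    Y = np.fft.rfft(y * taper, axis=1)
    sxy = (X * np.conj(Y)).sum(axis=0)
    sxx = (np.abs(X) ** 2).sum(axis=0)
    syy = (np.abs(Y) ** 2).sum(axis=0)
    denom = sxx * syy
    coh = np.zeros_like(sxx)
    nz = denom > 0
    coh[nz] = np.abs(sxy[nz]) ** 2 / denom[nz]
    freqs = np.fft.rfftfreq(x.shape[1], 1.0 / fs)
    keep = freqs <= fmax + 1e-9
    return CoherenceSpectrum(freqs[keep], np.clip(coh[keep], 0.0, 1.0),
                             x.shape[0], pair)


def segment_epoch(epoch: np.ndarray, fs: float, seg_len: float = 1.0,
                  overlap: float = 0.0) -> np.ndarray:
    """Slice a 1-D epoch into (possibly overlapping) fixed-length segments."""
    n = int(round(seg_len * fs))
    step = max(1, int(round(n * (1.0 - overlap))))
    starts = range(0, epoch.size - n + 1, step)
    return np.stack([epoch[s:s + n] for s in starts])


def across_trial_cmc(trials, pairs: list[tuple[str, str]],
                     seg_len: float = 1.0, fmax: float = 60.0
                     ) -> dict[tuple[str, str], CoherenceSpectrum]:
    """Across-trial coherence per pair: 1-s non-overlapping Hann segments pooled over task epochs.

    ``trials`` is a :class:`~cmcdetect.preprocess.TrialSet`; only kept task
    trials contribute (an 8-s epoch yields 8 segments). EMG is rectified
    (absolute value) before segmentation. With 1-s segments the frequency
    resolution is 1 Hz.
    """
    task = trials.kept("task")
    if not task:
        raise ValueError("no kept task trials")
    out = {}
    for ch, mus in pairs:
        ci = trials.channel_labels.index(ch)
        mi = trials.muscle_labels.index(mus)
        xs = np.concatenate([segment_epoch(t.eeg[ci], trials.fs, seg_len)
                             for t in task])
        ys = np.concatenate([segment_epoch(np.abs(t.emg[mi]), trials.fs,
                                           seg_len) for t in task])
        out[(ch, mus)] = msc(xs, ys, trials.fs, fmax=fmax, pair=(ch, mus))
    return out


def characteristic_frequency(spec: CoherenceSpectrum,
                             band: tuple[float, float] = (13.0, 30.0)
                             ) -> float:
    """Beta-band frequency of maximal coherence (ties break to the lowest frequency)."""
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not np.any(mask):
        raise ValueError(f"spectrum does not cover the {band} Hz band")
    sub = spec.coh[mask]
    return float(spec.freqs[mask][int(np.argmax(sub))])  # argmax: first max


def single_trial_cmc(eeg_win: np.ndarray, emg_win: np.ndarray, fs: float,
                     f0: float, seg_len: float = 0.25, overlap: float = 0.5,
                     pair: tuple[str, str] | None = None) -> SingleTrialCMC:
    """Windowed coherence at f0 from half-overlapped 250-ms Hann segments.

    A 1-s window at 1 kHz yields 7 segments and a 4 Hz frequency grid; the
    value is taken at the grid frequency nearest ``f0`` (both frequencies are
    recorded). The EMG window is rectified here.
    """
    nseg = int(round(seg_len * fs))
    step = max(1, int(round(nseg * (1.0 - overlap))))
    if eeg_win.size < nseg + step:
        raise ValueError("window too short for two segments")
    xs = segment_epoch(np.asarray(eeg_win, float), fs, seg_len, overlap)
    ys = segment_epoch(np.abs(np.asarray(emg_win, float)), fs, seg_len,
                       overlap)
    spec = msc(xs, ys, fs, fmax=fs / 2, pair=pair)
    k = int(np.argmin(np.abs(spec.freqs - f0)))
    return SingleTrialCMC(float(spec.coh[k]), float(spec.freqs[k]), f0, pair)
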