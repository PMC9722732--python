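"""EMG onset detection: Teager–Kaiser energy, envelope extraction, Hodges–Bui.

The per-trial EMG onset of the target muscle is the temporal reference for
every detection-latency metric downstream. The pipeline is: band-pass the
EMG 30–300 Hz, apply the Teager–Kaiser energy operator (TKEO) to sharpen the
activation edge, rectify, low-pass at 50 Hz to obtain the envelope, then run
the Hodges–Bui detector (sliding test-window mean against baseline
mean + h·SD with a persistence requirement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["OnsetAnnotation", "tkeo", "emg_envelope", "hodges_bui_onset",
           "plot_onset_qc"]


@dataclass
class OnsetAnnotation:
    """Detected onset of one task trial, in seconds from the cue."""

    trial: int
    onset_time: float | None
    baseline_window: tuple[float, float]
    test_window: float
    h: float


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager–Kaiser energy operator ψ[n] = x[n]² − x[n−1]·x[n+1].

    Interior samples follow the formula; the two endpoints copy their
    adjacent interior value so the output matches the input length. For a
    sinusoid A·sin(ωn) the output is the constant A²·sin²(ω), which is why
    the operator tracks instantaneous amplitude–frequency energy.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def emg_envelope(x: np.ndarray, fs: float,
                 band: tuple[float, float] = (30.0, 300.0),
                 lowpass: float = 50.0, order: int = 4) -> np.ndarray:
    """Amplitude envelope: band-pass → TKEO → rectify → low-pass (all zero phase).

    The returned envelope is non-negative (small negative low-pass ripple is
    clipped to zero).
    """
    hi = min(band[1], 0.45 * fs)
    sos = signal.butter(order, (band[0], hi), btype="bandpass", fs=fs,
                        output="sos")
    y = signal.sosfiltfilt(sos, np.asarray(x, float))
    y = np.abs(tkeo(y))
    sos = signal.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, y)
    return np.clip(env, 0.0, None)


def hodges_bui_onset(env: np.ndarray, fs: float,
                     baseline_window: tuple[float, float] = (0.5, 3.5),
                     test_window: float = 0.05, h: float = 3.0,
                     search_start: float = 3.5,
                     trial: int = -1) -> OnsetAnnotation:
    """Hodges–Bui onset on an envelope: first test window whose mean clears baseline.

    The baseline mean μ_b and SD σ_b come from ``baseline_window`` (defaults
    to [0.5, 3.5] s, inside the preparatory period). The onset is the start
    time of the first sliding window of length ``test_window`` whose mean
    exceeds μ_b + h·σ_b, searched from ``search_start`` (0.5 s before the go
    cue by default, to skip cue transients); ``onset_time`` is ``None`` when
    no window qualifies. A degenerate baseline (σ_b = 0) falls back to
    σ_b = 1e-6·μ_b with a warning.
    """
    env = np.asarray(env, float)
    b0, b1 = (int(round(t * fs)) for t in baseline_window)
    if not 0 <= b0 < b1 <= env.size:
        raise ValueError("baseline window outside the trial")
    base = env[b0:b1]
    mu, sd = float(base.mean()), float(base.std())
    floor = 1e-6 * max(mu, 1e-30)  # guard against (numerically) flat baselines
    if sd < floor:
        warnings.warn("degenerate baseline (near-zero SD); using 1e-6·mean")
        sd = floor
    thr = mu + h * sd
    w = max(1, int(round(test_window * fs)))
    # sliding-window means via cumulative sum
    c = np.concatenate([[0.0], np.cumsum(env)])
    means = (c[w:] - c[:-w]) / w  # means[i] over [i, i+w)
    start = max(0, int(round(search_start * fs)))
    idx = np.flatnonzero(means[start:] > thr)
    onset = (start + int(idx[0])) / fs if idx.size else None
    return OnsetAnnotation(trial, onset, baseline_window, test_window, h)


def plot_onset_qc(env: np.ndarray, fs: float, annotation: OnsetAnnotation,
                  path: str) -> None:
    """Export a per-trial QC figure: envelope, baseline band and detected onset.

    Batch runs trust the detector; this plot is the stand-in for interactive
    visual validation of each trial's onset.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(env.size) / fs
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, env, lw=0.8, label="envelope")
    b0, b1 = annotation.baseline_window
    mu = env[int(b0 * fs):int(b1 * fs)].mean()
    sd = env[int(b0 * fs):int(b1 * fs)].std()
    ax.axvspan(b0, b1, alpha=0.15, color="gray", label="baseline")
    ax.axhline(mu + annotation.h * sd, color="k", ls=":", lw=0.8,
               label="threshold")
    if annotation.onset_time is not None:
        ax.axvline(annotation.onset_time, color="r", lw=1.2,
                   label=f"onset {annotation.onset_time:.3f} s")
    ax.set_xlabel("time from cue (s)")
    ax.set_ylabel("TKEO envelope (a.u.)")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(f"trial {annotation.trial}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
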