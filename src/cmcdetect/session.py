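"""Session container: simultaneous EEG + EMG recordings with cue markers.

A :class:`Session` holds the continuous signals of one run (block design of
task and rest trials), the cue times marking trial starts, and — for synthetic
sessions — the planted ground truth (true EMG onsets, coupled EEG–EMG pair,
coupling frequency). Sessions round-trip through an HDF5 container with groups
``/eeg``, ``/emg``, ``/markers`` and ``/truth``; EEG from real recordings can
be read from BrainVision files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Session", "SessionTruth", "write_session", "read_session",
           "read_brainvision_eeg"]


@dataclass
class SessionTruth:
    """Planted ground truth of a synthetic session.

    ``onsets`` maps trial index (position in the trial sequence) to the true
    EMG onset in seconds from that trial's cue. ``coupled_pairs`` lists the
    (EEG channel, muscle) pairs carrying the planted beta-band coupling.
    """

    onsets: dict[int, float] = field(default_factory=dict)
    coupled_pairs: list[tuple[str, str]] = field(default_factory=list)
    coupling_freq: float | None = None


@dataclass
class Session:
    """One recording run: continuous EEG (µV) and EMG (mV) plus trial markers."""

    eeg: np.ndarray  # (n_channels, n_samples) at fs_eeg, µV
    emg: np.ndarray  # (n_muscles, n_samples) at fs_emg, mV
    fs_eeg: float
    fs_emg: float
    channel_labels: list[str]
    muscle_labels: list[str]
    cue_times: np.ndarray  # seconds, one per trial
    trial_labels: list[str]  # 'task' | 'rest'
    mvc: dict[str, float] = field(default_factory=dict)  # per-muscle MVC (mV RMS)
    truth: SessionTruth | None = None

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != len(self.channel_labels):
            raise ValueError("EEG rows must match channel_labels")
        if self.emg.shape[0] != len(self.muscle_labels):
            raise ValueError("EMG rows must match muscle_labels")
        if len(self.cue_times) != len(self.trial_labels):
            raise ValueError("one cue per trial required")

    @property
    def n_trials(self) -> int:
        return len(self.trial_labels)

    def trial_duration(self, index: int, task_dur: float = 8.0,
                       rest_dur: float = 4.0) -> float:
        return task_dur if self.trial_labels[index] == "task" else rest_dur

    def copy(self) -> "Session":
        truth = None
        if self.truth is not None:
            truth = SessionTruth(dict(self.truth.onsets),
                                 list(self.truth.coupled_pairs),
                                 self.truth.coupling_freq)
        return Session(self.eeg.copy(), self.emg.copy(), self.fs_eeg,
                       self.fs_emg, list(self.channel_labels),
                       list(self.muscle_labels), self.cue_times.copy(),
                       list(self.trial_labels), dict(self.mvc), truth)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to the HDF5 container (groups /eeg, /emg, /markers, /truth)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("eeg")
        g.create_dataset("data", data=session.eeg, compression="gzip")
        g.attrs["fs"] = session.fs_eeg
        g.attrs["unit"] = "uV"
        g.create_dataset("labels", data=np.array(session.channel_labels, dtype="S"))
        g = f.create_group("emg")
        g.create_dataset("data", data=session.emg, compression="gzip")
        g.attrs["fs"] = session.fs_emg
        g.attrs["unit"] = "mV"
        g.create_dataset("labels", data=np.array(session.muscle_labels, dtype="S"))
        if session.mvc:
            g.create_dataset("mvc", data=np.array(
                [session.mvc[m] for m in session.muscle_labels]))
        g = f.create_group("markers")
        g.create_dataset("cue_times", data=np.asarray(session.cue_times, float))
        g.create_dataset("trial_labels",
                         data=np.array(session.trial_labels, dtype="S"))
        if session.truth is not None:
            g = f.create_group("truth")
            idx = sorted(session.truth.onsets)
            g.create_dataset("onset_trials", data=np.array(idx, dtype=np.int64))
            g.create_dataset("onset_times", data=np.array(
                [session.truth.onsets[i] for i in idx], float))
            pairs = ["%s|%s" % p for p in session.truth.coupled_pairs]
            g.create_dataset("coupled_pairs", data=np.array(pairs, dtype="S"))
            if session.truth.coupling_freq is not None:
                g.attrs["coupling_freq"] = session.truth.coupling_freq


def read_session(path: str | Path) -> Session:
    """Read a session from the HDF5 container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        for group in ("eeg", "emg", "markers"):
            if group not in f:
                raise ValueError(f"not a session container: missing /{group}")
        if "cue_times" not in f["markers"]:
            raise ValueError("missing markers: expected /markers/cue_times "
                             "and /markers/trial_labels")
        eeg = f["eeg/data"][()]
        emg = f["emg/data"][()]
        fs_eeg = float(f["eeg"].attrs["fs"])
        fs_emg = float(f["emg"].attrs["fs"])
        ch = [s.decode() for s in f["eeg/labels"][()]]
        mus = [s.decode() for s in f["emg/labels"][()]]
        cues = f["markers/cue_times"][()]
        labels = [s.decode() for s in f["markers/trial_labels"][()]]
        mvc = {}
        if "mvc" in f["emg"]:
            vals = f["emg/mvc"][()]
            mvc = {m: float(v) for m, v in zip(mus, vals)}
        truth = None
        if "truth" in f:
            g = f["truth"]
            onsets = {int(i): float(t) for i, t in
                      zip(g["onset_trials"][()], g["onset_times"][()])}
            pairs = [tuple(s.decode().split("|")) for s in g["coupled_pairs"][()]]
            cf = g.attrs.get("coupling_freq")
            truth = SessionTruth(onsets, pairs,
                                 float(cf) if cf is not None else None)
    return Session(eeg, emg, fs_eeg, fs_emg, ch, mus,
                   np.asarray(cues, float), labels, mvc, truth)


def read_brainvision_eeg(vhdr_path: str | Path):
    """Read continuous EEG and marker times from a BrainVision header file.

    Returns ``(data_uV, fs, channel_labels, marker_times_s)``. Stimulus-type
    markers are interpreted as cue times. Requires the companion ``.eeg`` and
    ``.vmrk`` files next to the header.
    """
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True,
                                      verbose="error")
    data = raw.get_data() * 1e6  # V -> µV
    events, _ = mne.events_from_annotations(raw, verbose="error")
    marker_times = events[:, 0] / raw.info["sfreq"]
    return data, float(raw.info["sfreq"]), list(raw.ch_names), marker_times
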