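"""HDF5/CSV persistence for intermediate pipeline products."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from cmcdetect.features import FeatureMatrix
from cmcdetect.preprocess import Trial, TrialSet

__all__ = ["write_trialset", "read_trialset", "write_features",
           "read_features", "write_onsets_csv", "read_onsets_csv"]


def write_trialset(trials: TrialSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = trials.fs
        f.create_dataset("channel_labels",
                         data=np.array(trials.channel_labels, dtype="S"))
        f.create_dataset("muscle_labels",
                         data=np.array(trials.muscle_labels, dtype="S"))
        if trials.mvc:
            f.create_dataset("mvc", data=np.array(
                [trials.mvc[m] for m in trials.muscle_labels]))
        for t in trials.trials:
            g = f.create_group(f"trial_{t.index:04d}")
            g.attrs["index"] = t.index
            g.attrs["label"] = t.label
            g.attrs["status"] = t.status
            g.attrs["reason"] = t.reason or ""
            g.attrs["interpolated"] = ",".join(t.interpolated_channels)
            g.create_dataset("eeg", data=t.eeg, compression="gzip")
            g.create_dataset("emg", data=t.emg, compression="gzip")
        if trials.truth is not None:
            g = f.create_group("truth")
            idx = sorted(trials.truth.onsets)
            g.create_dataset("onset_trials", data=np.array(idx, np.int64))
            g.create_dataset("onset_times", data=np.array(
                [trials.truth.onsets[i] for i in idx]))
            g.create_dataset("coupled_pairs", data=np.array(
                ["%s|%s" % p for p in trials.truth.coupled_pairs], dtype="S"))
            if trials.truth.coupling_freq is not None:
                g.attrs["coupling_freq"] = trials.truth.coupling_freq


def read_trialset(path: str | Path) -> TrialSet:
    from cmcdetect.session import SessionTruth

    with h5py.File(path, "r") as f:
        ch = [s.decode() for s in f["channel_labels"][()]]
        mus = [s.decode() for s in f["muscle_labels"][()]]
        mvc = {}
        if "mvc" in f:
            mvc = {m: float(v) for m, v in zip(mus, f["mvc"][()])}
        trials = []
        for key in sorted(k for k in f if k.startswith("trial_")):
            g = f[key]
            interp = [c for c in g.attrs["interpolated"].split(",") if c]
            trials.append(Trial(int(g.attrs["index"]), str(g.attrs["label"]),
                                g["eeg"][()], g["emg"][()],
                                str(g.attrs["status"]),
                                str(g.attrs["reason"]) or None, interp))
        truth = None
        if "truth" in f:
            g = f["truth"]
            onsets = {int(i): float(t) for i, t in
                      zip(g["onset_trials"][()], g["onset_times"][()])}
            pairs = [tuple(s.decode().split("|"))
                     for s in g["coupled_pairs"][()]]
            cf = g.attrs.get("coupling_freq")
            truth = SessionTruth(onsets, pairs,
                                 float(cf) if cf is not None else None)
        return TrialSet(trials, float(f.attrs["fs"]), ch, mus, mvc, truth)


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=fm.X)
        f.create_dataset("y", data=fm.y)
        f.create_dataset("trial_indices", data=fm.trial_indices)
        f.create_dataset("pairs", data=np.array(
            ["%s|%s" % p for p in fm.pairs], dtype="S"))
        f.create_dataset("f0", data=np.array(
            [fm.f0[p] for p in fm.pairs]))
        if fm.movement:
            f.attrs["movement"] = fm.movement
        if fm.side:
            f.attrs["side"] = fm.side


def read_features(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        pairs = [tuple(s.decode().split("|")) for s in f["pairs"][()]]
        f0 = {p: float(v) for p, v in zip(pairs, f["f0"][()])}
        return FeatureMatrix(f["X"][()], f["y"][()].astype(bool), pairs,
                             f["trial_indices"][()], f0,
                             f.attrs.get("movement"), f.attrs.get("side"))


def write_onsets_csv(onsets: dict[int, float | None],
                     path: str | Path) -> None:
    rows = [{"trial": k, "onset_s": v if v is not None else np.nan,
             "flagged": v is None} for k, v in sorted(onsets.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_onsets_csv(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path)
    return {int(r.trial): float(r.onset_s) for r in df.itertuples()
            if not np.isnan(r.onset_s)}
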