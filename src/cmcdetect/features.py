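"""Anatomical pair restriction and Fisher-criterion feature selection.

The candidate feature space is restricted to pairs joining the target muscle
(extensor digitorum for finger extension, flexor digitorum superficialis for
grasping, on the moving side) with sensorimotor-strip EEG channels over the
hemisphere contralateral to the moving hand (10-20 convention: odd-numbered
labels = left hemisphere = contralateral to the right hand; midline excluded).
The two most discriminant pairs by the two-class Fisher ratio

    J = (μ_task − μ_rest)² / (s²_task + s²_rest)

are selected per movement × side (sample variances, n−1 denominator).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from cmcdetect.cmc import single_trial_cmc
from cmcdetect.preprocess import SENSORIMOTOR_CHANNELS, TrialSet

__all__ = ["FeatureMatrix", "restrict_pairs", "fisher_score", "fisher_rank",
           "build_feature_matrix", "target_muscle_for"]

TARGET_MUSCLE = {"ext": "ED", "grasp": "FD"}


def target_muscle_for(movement: str, side: str) -> str:
    """Target-muscle label for a movement type and moving side ('ED_R' etc.)."""
    movement = movement.lower()
    if movement not in TARGET_MUSCLE:
        raise ValueError(f"movement must be 'ext' or 'grasp', got {movement!r}")
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    return f"{TARGET_MUSCLE[movement]}_{side}"


def restrict_pairs(channel_labels: list[str], muscle_labels: list[str],
                   movement: str, side: str) -> list[tuple[str, str]]:
    """Candidate EEG–EMG pairs: contralateral sensorimotor channels × target muscle.

    ``side`` is the moving hand; the contralateral hemisphere carries
    odd-numbered labels for the right hand and even-numbered for the left.
    Midline (z) channels are never selected.
    """
    muscle = target_muscle_for(movement, side)
    if muscle not in muscle_labels:
        raise ValueError(f"target muscle {muscle!r} not among muscle labels")
    want_odd = side == "R"
    eeg = []
    for ch in channel_labels:
        if ch not in SENSORIMOTOR_CHANNELS:
            raise ValueError(f"unknown sensorimotor channel {ch!r}")
        m = re.fullmatch(r"([A-Za-z]+)(\d+|z)", ch)
        if m is None or m.group(2) == "z":
            continue  # midline: neither hemisphere
        if (int(m.group(2)) % 2 == 1) == want_odd:
            eeg.append(ch)
    return [(ch, muscle) for ch in eeg]


def fisher_score(task_values: np.ndarray, rest_values: np.ndarray) -> float:
    """Two-class Fisher ratio of one feature (sample variances, ddof=1).

    Degenerate case: zero variance in both classes gives 0 for equal means
    and +inf for distinct means (perfect separation).
    """
    t = np.asarray(task_values, float)
    r = np.asarray(rest_values, float)
    if t.size < 2 or r.size < 2:
        raise ValueError("need at least 2 observations per class")
    num = (t.mean() - r.mean()) ** 2
    den = t.var(ddof=1) + r.var(ddof=1)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / den)


def fisher_rank(features: np.ndarray, labels: np.ndarray,
                pairs: list[tuple[str, str]], n_select: int = 2
                ) -> list[tuple[tuple[str, str], float]]:
    """Rank candidate pairs by Fisher score, descending; return the top ``n_select``.

    ``features`` is (observations × candidate pairs), ``labels`` a boolean
    array (True = task). Ties break deterministically by candidate order.
    """
    y = np.asarray(labels, bool)
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    scores = np.array([fisher_score(features[y, j], features[~y, j])
                       for j in range(features.shape[1])])
    order = np.argsort(-scores, kind="stable")
    return [(pairs[j], float(scores[j])) for j in order[:n_select]]


@dataclass
class FeatureMatrix:
    """Observations × selected CMC features with task/rest labels."""

    X: np.ndarray  # (n_obs, n_features)
    y: np.ndarray  # bool, True = task
    pairs: list[tuple[str, str]]
    trial_indices: np.ndarray  # session trial index per observation
    f0: dict[tuple[str, str], float] = field(default_factory=dict)
    movement: str | None = None
    side: str | None = None

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[rows], self.y[rows], list(self.pairs),
                             self.trial_indices[rows], dict(self.f0),
                             self.movement, self.side)


def build_feature_matrix(trials: TrialSet, pairs: list[tuple[str, str]],
                         f0: dict[tuple[str, str], float],
                         task_window: tuple[float, float] = (5.0, 6.0),
                         rest_window: tuple[float, float] = (2.0, 3.0),
                         ) -> FeatureMatrix:
    """Whole-interval CMC features: one observation per kept trial.

    Task observations use the 1-s window [5, 6] s of the trial (inside the
    holding phase), rest observations the window [2, 3] s, per the offline
    analysis protocol; each column is the windowed coherence of one pair at
    (the nearest bin to) its characteristic frequency.
    """
    rows, ys, idx = [], [], []
    for t in trials.kept():
        w = task_window if t.label == "task" else rest_window
        s0, s1 = (int(round(x * trials.fs)) for x in w)
        feats = []
        for pair in pairs:
            ci = trials.channel_labels.index(pair[0])
            mi = trials.muscle_labels.index(pair[1])
            feats.append(single_trial_cmc(t.eeg[ci, s0:s1], t.emg[mi, s0:s1],
                                          trials.fs, f0[pair],
                                          pair=pair).value)
        rows.append(feats)
        ys.append(t.label == "task")
        idx.append(t.index)
    return FeatureMatrix(np.array(rows), np.array(ys, bool), list(pairs),
                         np.array(idx), dict(f0))
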