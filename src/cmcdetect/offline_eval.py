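"""Offline movement-vs-rest classification with Monte-Carlo cross-validation.

Ten random stratified 80/20 resamples; in each, a linear-kernel SVM (C = 1)
is fit on training features standardized by the training-split mean/SD, and
AUC (from decision values), accuracy, sensitivity and specificity are
computed on the held-out observations. If task and rest counts differ by
three or more, the majority class is randomly subsampled to the minority
size once, before cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cmcdetect.features import FeatureMatrix

__all__ = ["OfflineCVResult", "balance_classes", "cross_validate",
           "confusion_metrics", "make_classifier"]


def make_classifier():
    """The classification model: training-split standardization + linear SVM."""
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def balance_classes(fm: FeatureMatrix,
                    seed: int | np.random.Generator = 0) -> FeatureMatrix:
    """Subsample the majority class when the class imbalance is 3 or more.

    If ``|n_task − n_rest| >= 3`` the majority class is reduced to the
    minority size by seeded sampling without replacement; otherwise the
    matrix is returned unchanged.
    """
    n_task = int(fm.y.sum())
    n_rest = int((~fm.y).sum())
    if n_task == 0 or n_rest == 0:
        raise ValueError("both classes must be present")
    if abs(n_task - n_rest) < 3:
        return fm
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    n_keep = min(n_task, n_rest)
    maj = fm.y if n_task > n_rest else ~fm.y
    maj_idx = np.flatnonzero(maj)
    keep = set(rng.choice(maj_idx, size=n_keep, replace=False).tolist())
    rows = np.array([i for i in range(fm.y.size)
                     if not maj[i] or i in keep])
    return fm.subset(rows)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from a confusion table."""
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


@dataclass
class OfflineCVResult:
    """Per-iteration and mean offline classification metrics."""

    auc: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    sensitivity: list[float] = field(default_factory=list)
    specificity: list[float] = field(default_factory=list)
    seed: int | None = None
    n_iterations: int = 0
    balancing_log: str | None = None
    splits: list[np.ndarray] = field(default_factory=list)  # training rows

    def mean(self, metric: str) -> float:
        return float(np.mean(getattr(self, metric)))

    def summary(self) -> dict[str, float]:
        return {m: self.mean(m) for m in
                ("auc", "accuracy", "sensitivity", "specificity")}


def cross_validate(fm: FeatureMatrix, n_iter: int = 10, seed: int = 0,
                   train_frac: float = 0.8) -> OfflineCVResult:
    """Monte-Carlo cross-validation: ``n_iter`` random stratified 80/20 splits.

    Each training split holds equal task and rest counts
    (``train_frac``·n_obs observations in total, half per class); the
    remaining observations form the test split. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    y = fm.y
    n_task, n_rest = int(y.sum()), int((~y).sum())
    if min(n_task, n_rest) < 5:
        raise ValueError("need at least 5 observations per class")
    half = int(np.floor(train_frac * y.size / 2))
    half = min(half, n_task - 1, n_rest - 1)  # keep both classes in the test set
    task_idx = np.flatnonzero(y)
    rest_idx = np.flatnonzero(~y)
    res = OfflineCVResult(seed=seed, n_iterations=n_iter)
    for _ in range(n_iter):
        tr = np.concatenate([rng.choice(task_idx, half, replace=False),
                             rng.choice(rest_idx, half, replace=False)])
        te = np.setdiff1d(np.arange(y.size), tr)
        res.splits.append(tr)
        clf = make_classifier()
        clf.fit(fm.X[tr], y[tr])
        scores = clf.decision_function(fm.X[te])
        pred = clf.predict(fm.X[te])
        yt = y[te]
        tp = int(np.sum(pred & yt))
        fn = int(np.sum(~pred & yt))
        tn = int(np.sum(~pred & ~yt))
        fp = int(np.sum(pred & ~yt))
        m = confusion_metrics(tp, fn, tn, fp)
        res.auc.append(float(roc_auc_score(yt, scores)))
        res.accuracy.append(m["accuracy"])
        res.sensitivity.append(m["sensitivity"])
        res.specificity.append(m["specificity"])
    return res
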