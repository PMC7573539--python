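"""Shrinkage-LDA decoding of condition and direction.

A shrinkage-regularized linear discriminant (pooled within-class
covariance with analytic Ledoit-Wolf shrinkage toward scaled identity) is
fitted per time-point under leave-one-trial-out cross-validation, for
single-time-point features (channels at time t) or windowed features
(channels x ``window_len`` trailing time-points). Chance level is
estimated per subject by re-running the full cross-validation on
label-shuffled data and taking the 95th percentile of the shuffle
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import Epochs
from .encoding import shrinkage_covariance


class ShrinkageLda(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis with shrinkage-regularized covariance.

    The pooled within-class covariance is estimated with analytic
    shrinkage toward a scaled identity (``shrinkage=None``) or with a
    fixed intensity in [0, 1]; ``shrinkage=1`` reduces the classifier to
    nearest class mean. Multi-class problems use one linear score per
    class with a shared covariance and an arg-max decision.
    """

    def __init__(self, shrinkage: float | None = None, priors: str = "uniform"):
        self.shrinkage = shrinkage
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be trials x features matching y")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 trials")
        self.classes_ = classes
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in classes])
        centered = np.concatenate(
            [X[y == c] - m for c, m in zip(classes, self.means_)]
        )
        cov, self.gamma_ = shrinkage_covariance(
            centered, assume_centered=True, shrinkage=self.shrinkage
        )
        self.covariance_ = cov
        if self.priors == "uniform":
            log_prior = np.zeros(classes.size)
        else:
            log_prior = np.log(counts / counts.sum())
        w = np.linalg.solve(cov, self.means_.T).T        # K x p
        self.coef_ = w
        self.intercept_ = -0.5 * np.sum(w * self.means_, axis=1) + log_prior
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        scores = X @ self.coef_.T + self.intercept_
        if self.classes_.size == 2:
            return scores[:, 1] - scores[:, 0]
        return scores

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = X @ self.coef_.T + self.intercept_
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        scores = X @ self.coef_.T + self.intercept_
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        return p / p.sum(axis=1, keepdims=True)


def loto_predictions(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None = None
) -> np.ndarray:
    """Leave-one-trial-out predictions: exactly N folds, each trial tested
    once on a model trained on the other N-1 trials."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = ShrinkageLda(shrinkage=shrinkage).fit(X[train], y[train])
        preds[i] = clf.predict(X[i : i + 1])[0]
    return preds


def loto_accuracy(X, y, shrinkage: float | None = None) -> float:
    return float(np.mean(loto_predictions(X, y, shrinkage) == np.asarray(y)))


@dataclass
class AccuracyCurve:
    """Per-time-point cross-validated accuracies for one subject."""

    times: np.ndarray
    accuracy: np.ndarray             # NaN where features are undefined
    predictions: np.ndarray          # trials x times (object labels)
    labels: np.ndarray
    mode: str                        # 'single' | 'windowed'
    alignment: str
    window_len: int = 1
    significance_level: float | None = None

    def peak(self, interval: tuple[float, float] | None = None):
        """(peak accuracy, peak time) within the test interval."""
        sel = np.isfinite(self.accuracy)
        if interval is not None:
            sel &= (self.times >= interval[0]) & (self.times <= interval[1])
        if not np.any(sel):
            raise ValueError("empty test interval")
        cand = np.flatnonzero(sel)
        best = cand[np.argmax(self.accuracy[cand])]
        return float(self.accuracy[best]), float(self.times[best])

    def confusion_at(self, time: float) -> np.ndarray:
        """Confusion matrix (rows = true, cols = predicted, counts) at the
        time-point closest to ``time``."""
        t = int(np.argmin(np.abs(self.times - time)))
        classes = np.unique(self.labels)
        lut = {c: i for i, c in enumerate(classes)}
        cm = np.zeros((classes.size, classes.size), dtype=int)
        for yt, yp in zip(self.labels, self.predictions[:, t]):
            cm[lut[yt], lut[yp]] += 1
        return cm


def _features_at(data: np.ndarray, t: int, mode: str, window_len: int):
    """Feature matrix for time-point t; None if history is insufficient."""
    if mode == "single":
        return data[:, :, t]
    if mode == "windowed":
        if t < window_len - 1:
            return None
        return data[:, :, t - window_len + 1 : t + 1].reshape(len(data), -1)
    raise ValueError("mode must be 'single' or 'windowed'")


def crossval_accuracy_curve(
    epochs: Epochs | np.ndarray,
    labels: np.ndarray,
    mode: str = "single",
    window_len: int = 6,
    shrinkage: float | None = None,
    times: np.ndarray | None = None,
    alignment: str = "",
) -> AccuracyCurve:
    """Leave-one-trial-out accuracy at every time-point.

    Windowed features are the channels at the current and the
    ``window_len - 1`` preceding time-points (e.g. 64 channels x 6
    time-points = 384 features); time-points without sufficient history
    get NaN accuracy.
    """
    if isinstance(epochs, Epochs):
        data = epochs.data
        times = epochs.times if times is None else times
        alignment = alignment or epochs.alignment
    else:
        data = np.asarray(epochs, dtype=float)
        if times is None:
            times = np.arange(data.shape[2], dtype=float)
    labels = np.asarray(labels)
    n, _, n_t = data.shape
    if n < 10:
        raise ValueError("need at least 10 trials for the accuracy curve")
    if len(labels) != n:
        raise ValueError("label count must match trial count")
    acc = np.full(n_t, np.nan)
    preds = np.full((n, n_t), labels[0], dtype=labels.dtype)
    for t in range(n_t):
        feats = _features_at(data, t, mode, window_len)
        if feats is None:
            continue
        p = loto_predictions(feats, labels, shrinkage)
        preds[:, t] = p
        acc[t] = np.mean(p == labels)
    return AccuracyCurve(
        times=np.asarray(times, dtype=float),
        accuracy=acc,
        predictions=preds,
        labels=labels,
        mode=mode,
        alignment=alignment,
        window_len=window_len if mode == "windowed" else 1,
    )


def shuffle_significance_level(
    features: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    shrinkage: float | None = None,
    return_accuracies: bool = False,
):
    """Subject-specific chance threshold from label shuffling.

    Class labels are permuted across trials and the full leave-one-trial-
    out cross-validation is repeated; the threshold is the given
    percentile of the shuffle accuracies. ``features`` is a trials x
    features matrix (e.g. the channels at one reference time-point).
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(len(labels))
        accs[i] = loto_accuracy(features, labels[perm], shrinkage)
    thr = float(np.percentile(accs, percentile))
    if return_accuracies:
        return thr, accs
    return thr


@dataclass
class PeakSummary:
    peaks: pd.DataFrame                       # subject, alignment, peak, time
    confusions: dict = field(default_factory=dict)
    paired_differences: np.ndarray | None = None


def summarize_peaks(
    curves: dict[tuple[int, str], AccuracyCurve],
    intervals: dict[str, tuple[float, float]],
) -> PeakSummary:
    """Per-subject peak accuracies/times within the test interval (cue to
    movement offset), confusion matrices at the peak, and the paired
    per-subject peak difference between the two alignments."""
    rows = []
    confusions = {}
    for (subject, alignment), curve in sorted(curves.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        pk, pt = curve.peak(intervals.get(alignment))
        rows.append(
            {
                "subject": subject,
                "alignment": alignment,
                "peak_accuracy": pk,
                "peak_time": pt,
            }
        )
        confusions[(subject, alignment)] = curve.confusion_at(pt)
    peaks = pd.DataFrame(rows)
    diffs = None
    aligns = sorted(peaks["alignment"].unique())
    if len(aligns) == 2:
        a = peaks[peaks.alignment == aligns[0]].sort_values("subject")
        b = peaks[peaks.alignment == aligns[1]].sort_values("subject")
        if len(a) == len(b) and len(a) >= 2:
            diffs = (
                a["peak_accuracy"].to_numpy() - b["peak_accuracy"].to_numpy()
            )
    return PeakSummary(peaks=peaks, confusions=confusions, paired_differences=diffs)
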