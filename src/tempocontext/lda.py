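"""Time-resolved diagonal-covariance LDA decoding with shuffle correction.

A binary side-of-plane label is decoded from sensor amplitudes at each
time point with ten-fold cross-validated linear discriminant analysis
using a pooled *diagonal* covariance ("diaglinear" semantics) and equal
priors. Slow across-trial drift in the recordings inflates apparent
accuracy for repeat trials (temporally proximal trials look alike to the
classifier); the shuffle-label baseline — the mean accuracy over
label-shuffled reruns of the identical fold structure — captures exactly
that stimulus-unrelated component, and subtracting it yields
chance-centered corrected accuracy. A cross-trial high-pass filter is
provided as an alternative drift control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

VAR_FLOOR = 1e-12


class DiagLinearDiscriminant(ClassifierMixin, BaseEstimator):
    """Gaussian linear discriminant with pooled diagonal covariance.

    Matches MATLAB ``classify(..., 'diaglinear')`` up to the priors, which
    default to equal here (the paradigm presents the two sides
    equiprobably). Fitted attributes: ``classes_``, ``means_`` (k x f),
    ``var_`` (f,), ``priors_``.
    """

    def __init__(self, priors="equal"):
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes in training data")
        n, f = X.shape
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        # pooled within-class variance per feature
        ss = np.zeros(f)
        for c, mu in zip(self.classes_, self.means_):
            d = X[y == c] - mu
            ss += np.einsum("ij,ij->j", d, d)
        var = ss / (n - self.classes_.size)
        if np.any(var <= VAR_FLOOR):
            warnings.warn("zero-variance feature(s); variance floored")
        self.var_ = np.maximum(var, VAR_FLOOR)
        if self.priors == "equal":
            self.priors_ = np.full(self.classes_.size, 1.0 / self.classes_.size)
        elif self.priors == "empirical":
            self.priors_ = counts / n
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        inv = 1.0 / self.var_
        # log-likelihood up to a shared constant
        return (X @ (self.means_ * inv).T
                - 0.5 * np.sum(self.means_ ** 2 * inv, axis=1)
                + np.log(self.priors_))

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]

    def decision_function(self, X):
        s = self._scores(X)
        return s[:, 1] - s[:, 0] if s.shape[1] == 2 else s


@dataclass
class AccuracyTimecourse:
    """Per-condition time-resolved classification accuracy."""

    times: np.ndarray
    accuracy: np.ndarray                  # (n_times,)
    condition: str = "all"
    n_trials: int = 0
    baseline: np.ndarray | None = None
    corrected: np.ndarray | None = field(default=None)

    def with_baseline(self, baseline):
        return AccuracyTimecourse(self.times, self.accuracy, self.condition,
                                  self.n_trials, baseline,
                                  self.accuracy - baseline)


def _make_folds(y, n_folds, random_state):
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k = min(n_folds, counts.min())
    if k < n_folds:
        warnings.warn(f"class too small for {n_folds} folds; using {k}")
    if k < 2:
        raise ValueError("need at least 2 trials per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    return list(skf.split(np.zeros(y.size), y))


def _cv_correct(data, y, folds):
    """Held-out correctness of every trial at every time point.

    ``data`` is (n_trials, n_sensors, n_times). The per-time-point
    classifier is fitted with vectorized pooled-diagonal statistics; fold
    assignment is fixed across time points.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    n, m, nt = data.shape
    correct = np.zeros((n, nt), dtype=bool)
    for train, test in folds:
        Xtr, ytr = data[train], y[train]
        i0, i1 = ytr == classes[0], ytr == classes[1]
        if not (i0.any() and i1.any()):
            raise RuntimeError("fold lost a class; refold with stratification")
        mu0 = Xtr[i0].mean(axis=0)            # (m, nt)
        mu1 = Xtr[i1].mean(axis=0)
        d0 = Xtr[i0] - mu0
        d1 = Xtr[i1] - mu1
        var = (np.einsum("nmt,nmt->mt", d0, d0)
               + np.einsum("nmt,nmt->mt", d1, d1)) / max(len(ytr) - 2, 1)
        var = np.maximum(var, VAR_FLOOR)
        # equal priors: decide by the sign of the pooled-diagonal LLR
        Xte = data[test]
        llr = np.einsum("nmt,mt->nt", Xte, (mu1 - mu0) / var) \
            - 0.5 * np.sum((mu1 ** 2 - mu0 ** 2) / var, axis=0)
        pred = np.where(llr > 0, classes[1], classes[0])
        correct[test] = pred == y[test][:, None]
    return correct


def lda_crossval_timecourse(epochs, labels, n_folds=10, random_state=0):
    """Cross-validated classification accuracy at every time point.

    Features are the sensor amplitudes at one time point; the stratified,
    seeded fold assignment is shared across time points. Accuracy is the
    mean over folds of per-fold accuracy.
    """
    y = np.asarray(labels)
    folds = _make_folds(y, n_folds, random_state)
    correct = _cv_correct(epochs.data, y, folds)
    acc = np.mean([correct[test].mean(axis=0) for _, test in folds], axis=0)
    return AccuracyTimecourse(times=epochs.times, accuracy=acc,
                              n_trials=y.size)


def micro_splits(labels):
    """Repeat/alternate masks derived from a binary label sequence.

    A trial is a repeat when its label equals the previous trial's label;
    the first trial belongs to neither split.
    """
    y = np.asarray(labels)
    rep = np.zeros(y.size, dtype=bool)
    alt = np.zeros(y.size, dtype=bool)
    same = y[1:] == y[:-1]
    rep[1:], alt[1:] = same, ~same
    return {"repeat": rep, "alternate": alt}


def meso_splits(labels):
    """Eight sequence-class masks from the four transitions ending at each trial."""
    from .context import combine_symmetric, enumerate_histories

    y = np.asarray(labels)
    table = combine_symmetric(enumerate_histories(5))
    codes = np.where(y[1:] == y[:-1], "R", "A")
    out = {r: np.zeros(y.size, dtype=bool) for r in range(1, 9)}
    for t in range(4, y.size):
        out[table["".join(codes[t - 4:t])]][t] = True
    return out


def _resolve_split_fn(split):
    if split is None:
        return lambda y: {"all": np.ones(np.asarray(y).size, dtype=bool)}
    if callable(split):
        return split
    if isinstance(split, str):
        if split == "micro":
            return micro_splits
        if split == "meso":
            return meso_splits
        raise ValueError(f"unknown split {split!r}")
    # fixed, label-independent condition assignment
    conds = np.asarray(split, dtype=object)
    values = [c for c in pd.unique(conds) if c is not None and c == c]

    def fixed(_y):
        return {c: conds == c for c in values}

    return fixed


def shuffle_baseline(epochs, labels, split=None, n_shuffles=100,
                     random_state=0, n_folds=10, min_trials=1):
    """Shuffle-label accuracy baselines and corrected accuracies.

    Reruns the identical cross-validation (same fold structure) with the
    trial labels permuted ``n_shuffles`` times; the baseline is the mean
    shuffled accuracy per condition. ``split`` defines the condition
    assignment: 'micro' / 'meso' recompute the split from the (possibly
    shuffled) label sequence — essential, because those conditions are
    functions of the labels and the drift confound expresses itself through
    them — while an explicit per-trial condition array stays fixed across
    shuffles. Returns ``condition -> AccuracyTimecourse`` with ``baseline``
    and ``corrected`` (= raw - baseline); conditions below ``min_trials``
    map to None.
    """
    if n_shuffles < 10:
        warnings.warn("fewer than 10 shuffles gives a noisy baseline")
    y = np.asarray(labels)
    rng = np.random.default_rng(random_state)
    folds = _make_folds(y, n_folds, random_state)
    split_fn = _resolve_split_fn(split)
    correct = _cv_correct(epochs.data, y, folds)
    raw_masks = split_fn(y)
    keys = list(raw_masks)
    base = {k: np.zeros(epochs.n_times) for k in keys}
    counts = {k: 0 for k in keys}
    for _ in range(n_shuffles):
        ys = y[rng.permutation(y.size)]
        corr_s = _cv_correct(epochs.data, ys, folds)
        masks_s = split_fn(ys)
        for k in keys:
            msk = masks_s.get(k)
            if msk is not None and msk.any():
                base[k] += corr_s[msk].mean(axis=0)
                counts[k] += 1
    out = {}
    for k in keys:
        msk = raw_masks[k]
        n_k = int(msk.sum())
        if n_k < min_trials:
            out[k] = None
            continue
        raw = AccuracyTimecourse(times=epochs.times,
                                 accuracy=correct[msk].mean(axis=0),
                                 condition=str(k), n_trials=n_k)
        out[k] = raw.with_baseline(base[k] / max(counts[k], 1))
    return out


def condition_split_accuracy(epochs, labels, split, n_folds=10,
                             n_shuffles=100, random_state=0, min_trials=10):
    """Per-condition accuracy curves with per-condition shuffle baselines.

    The classifier is trained once on all trials (cross-validated);
    accuracy is then assessed separately per condition. ``split`` is
    'micro', 'meso', a callable ``labels -> {condition: mask}``, or a fixed
    per-trial condition array. Conditions with fewer than ``min_trials``
    trials come back as None.
    """
    out = shuffle_baseline(epochs, labels, split=split, n_shuffles=n_shuffles,
                           random_state=random_state, n_folds=n_folds,
                           min_trials=min_trials)
    if all(v is None for v in out.values()):
        raise ValueError("no condition reaches the minimum trial count")
    return out


def highpass_epochs(epochs, cutoff_hz=0.7, trial_rate_hz=None, order=1):
    """High-pass the across-trial signal to remove slow drift.

    Epochs are short relative to the drift, so the filter runs across the
    trial axis at each (sensor, time) with the trial presentation rate as
    the effective sampling rate (default 1/0.3 s, the stimulus onset
    asynchrony of the stream). Temporal smearing across neighboring trials
    is an accepted side effect; downstream results should carry that
    caveat.
    """
    from dataclasses import replace

    rate = 1.0 / 0.3 if trial_rate_hz is None else float(trial_rate_hz)
    if cutoff_hz >= rate / 2.0:
        raise ValueError("cutoff at/above the trial-rate Nyquist")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate, output="sos")
    filt = signal.sosfiltfilt(sos, epochs.data, axis=0)
    return replace(epochs, data=filt)
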