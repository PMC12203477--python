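"""Movement-type classification from Movement-window spike counts.

Features are per-trial total spike counts in each channel over the 500 ms
response window of the trial's movement type.  Classification uses a Naive
Bayes classifier under full leave-one-out cross-validation; held-out
predictions are pooled into a confusion matrix per session and across
sessions.  Chance level is 25% for the four-movement balanced design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .somatotopy import MovementWindow, _trial_onset_bins
from .synthetic import MOVEMENTS, SessionBundle


class SpikeCountNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes over spike-count features with a fixed tie-break order.

    Parameters
    ----------
    emissions : 'gaussian' (default) or 'poisson'.  Gaussian emissions use a
        per-class variance floored at ``var_floor_abs + var_floor_rel *``
        (mean feature variance of the training set); the Poisson variant
        models each count feature with a per-class rate.
    class_order : explicit label order used for posterior tie-breaking;
        defaults to the canonical movement order when all labels are
        movements, else the sorted unique labels.

    Class priors are uniform (the task design is balanced by construction).
    """

    def __init__(
        self,
        emissions: str = "gaussian",
        var_floor_abs: float = 1e-9,
        var_floor_rel: float = 1e-3,
        class_order: tuple | None = None,
    ):
        self.emissions = emissions
        self.var_floor_abs = var_floor_abs
        self.var_floor_rel = var_floor_rel
        self.class_order = class_order

    def _resolve_classes(self, y: np.ndarray) -> np.ndarray:
        present = set(y.tolist())
        if self.class_order is not None:
            order = [c for c in self.class_order if c in present]
            if set(order) != present:
                raise ValueError("class_order does not cover the training labels")
            return np.asarray(order, dtype=object)
        if present <= set(MOVEMENTS):
            return np.asarray([m for m in MOVEMENTS if m in present], dtype=object)
        return np.unique(y)

    def fit(self, X: np.ndarray, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.emissions not in ("gaussian", "poisson"):
            raise ValueError(f"unknown emissions model: {self.emissions!r}")
        self.classes_ = self._resolve_classes(y)
        if any(np.sum(y == c) < 1 for c in self.classes_):
            raise ValueError("every class needs at least one training trial")
        means, variances = [], []
        for c in self.classes_:
            Xc = X[y == c]
            means.append(Xc.mean(axis=0))
            variances.append(Xc.var(axis=0, ddof=0))
        self.theta_ = np.stack(means)
        floor = self.var_floor_abs + self.var_floor_rel * X.var(axis=0, ddof=0).mean()
        self.var_ = np.maximum(np.stack(variances), floor)
        # Poisson rates need to be positive for the log-likelihood
        self.rate_ = np.maximum(self.theta_, 1e-6)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.emissions == "gaussian":
            ll = -0.5 * (
                np.log(2 * np.pi * self.var_[None])
                + (X[:, None, :] - self.theta_[None]) ** 2 / self.var_[None]
            )
        else:
            lam = self.rate_[None]
            ll = X[:, None, :] * np.log(lam) - lam - gammaln(X[:, None, :] + 1.0)
        return ll.sum(axis=2)  # uniform priors add a constant

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "theta_")
        jll = self._joint_log_likelihood(X)
        norm = np.logaddexp.reduce(jll, axis=1, keepdims=True)
        return jll - norm

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "theta_")
        # argmax takes the first maximum, i.e. the earliest class in order
        idx = np.argmax(self._joint_log_likelihood(X), axis=1)
        return self.classes_[idx]


@dataclass
class ClassificationResult:
    """Pooled held-out predictions with their confusion matrix."""

    y_true: np.ndarray
    y_pred: np.ndarray
    labels: tuple

    @property
    def confusion(self) -> np.ndarray:
        k = len(self.labels)
        idx = {c: i for i, c in enumerate(self.labels)}
        mat = np.zeros((k, k), dtype=int)
        for t, p in zip(self.y_true, self.y_pred):
            mat[idx[t], idx[p]] += 1
        return mat

    @property
    def n_trials(self) -> int:
        return len(self.y_true)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.labels),
                            columns=list(self.labels))


def features(
    session: SessionBundle,
    windows: dict[str, MovementWindow],
    active: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Movement-window spike-count features.

    Returns (X, y): X is trials x active-channels total counts in the
    response window of each trial's movement type, y the movement labels.
    """
    missing = [m for m in session.trials["movement_label"].unique() if m not in windows]
    if missing:
        raise ValueError(f"no response window for movements: {missing}")
    if active is None:
        active = np.ones(session.n_channels, dtype=bool)
    rows, labels = [], []
    for mv, win in windows.items():
        onset_bins = _trial_onset_bins(session, mv)
        start, stop = win.window_bins
        for b in onset_bins:
            rows.append(session.counts[active, b + start : b + stop].sum(axis=1))
            labels.append(mv)
    return np.asarray(rows), np.asarray(labels)


def loocv_classify(
    X: np.ndarray, y: np.ndarray, estimator: SpikeCountNB | None = None
) -> ClassificationResult:
    """Full leave-one-out cross-validation; held-out predictions pooled."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need >=2 trials per class for leave-one-out")
    estimator = SpikeCountNB() if estimator is None else estimator
    preds = np.empty(len(y), dtype=object)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        est = estimator.__class__(**estimator.get_params()).fit(X[mask], y[mask])
        preds[i] = est.predict(X[i : i + 1])[0]
        mask[i] = True
    labels = est.classes_
    return ClassificationResult(y_true=y, y_pred=preds, labels=tuple(labels))


def pool_confusions(results: list[ClassificationResult]) -> ClassificationResult:
    """Combine held-out predictions across sessions (same label set)."""
    labels = results[0].labels
    if any(r.labels != labels for r in results):
        raise ValueError("cannot pool results with different label sets")
    return ClassificationResult(
        y_true=np.concatenate([r.y_true for r in results]),
        y_pred=np.concatenate([r.y_pred for r in results]),
        labels=labels,
    )


def classify_session(
    session: SessionBundle,
    windows: dict[str, MovementWindow],
    active: np.ndarray | None = None,
    estimator: SpikeCountNB | None = None,
) -> ClassificationResult:
    """Windows -> features -> LOOCV, in one call."""
    X, y = features(session, windows, active)
    return loocv_classify(X, y, estimator)
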