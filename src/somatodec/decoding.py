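"""Velocity decoding by indirect optimal linear estimation, and click HMM.

A per-channel linear encoding model relates the z-scored firing rate f of
each channel to the presented velocities::

    f = b0 + bx*vx + by*vy + bz*vz + bg*vg

fit by ridge regression (intercept unpenalized).  Decoding inverts the
stacked encoding: v_hat = (B'B + gamma*I)^-1 B'(f - b0).  Performance is the
squared Pearson correlation between predicted and actual velocities over
movement-period bins, evaluated with full leave-one-trial-out
cross-validation, separately for the all-channels, medial-array and
lateral-array conditions.  Discrete click state is decoded with a two-state
hidden Markov model on a Fisher-discriminant projection of the z-rates,
evaluated leave-one-epoch-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .preprocessing import SmoothedRates, preprocess_session
from .synthetic import SessionBundle

#: inner-CV grid for the ridge penalty when no fixed value is given
LAMBDA_GRID = np.logspace(-3, 3, 7)
#: fraction of the per-trial peak speed above which a bin counts as movement
SPEED_MASK_FRACTION = 0.01


@dataclass
class EncodingModel:
    """Fitted per-channel encoding coefficients.

    ``intercepts`` has shape (channels,), ``slopes`` (channels, dims) in the
    order of ``dim_names``.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    dim_names: tuple[str, ...]
    ridge_lambda: float
    channel_idx: np.ndarray = field(default=None)


def _ridge_solve(V: np.ndarray, F: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Ridge LS of each column of F on [1, V]; intercept unpenalized.

    V: bins x dims, F: bins x channels.  Returns (intercepts, slopes).
    """
    n, d = V.shape
    X = np.column_stack([np.ones(n), V])
    G = X.T @ X
    if lam == 0.0 and np.linalg.matrix_rank(G) < d + 1:
        raise np.linalg.LinAlgError(
            "rank-deficient velocity design; use a positive ridge penalty"
        )
    P = np.eye(d + 1)
    P[0, 0] = 0.0
    W = np.linalg.solve(G + lam * P, X.T @ F)
    return W[0], W[1:].T


def fit_encoding(
    zrates: np.ndarray,
    velocities: np.ndarray,
    lam: float = 0.0,
    channel_idx: Optional[np.ndarray] = None,
    dim_names: Sequence[str] = ("vx", "vy", "vz", "vg"),
) -> EncodingModel:
    """Fit the per-channel linear encoding model.

    ``zrates`` is channels x bins (already restricted to fitting bins),
    ``velocities`` dims x bins.  All channels share the velocity design, so
    the ridge solution is computed for every channel in one solve.
    """
    F = np.asarray(zrates, dtype=float).T
    V = np.asarray(velocities, dtype=float).T
    if V.shape[0] != F.shape[0]:
        raise ValueError("zrates and velocities must share the bin axis")
    if V.shape[0] < V.shape[1] + 1:
        raise ValueError("need at least dims+1 bins to fit the encoding model")
    if not np.all(np.isfinite(V)):
        raise ValueError("velocities must be finite")
    b0, B = _ridge_solve(V, F, lam)
    return EncodingModel(
        intercepts=b0,
        slopes=B,
        dim_names=tuple(dim_names[: V.shape[1]]),
        ridge_lambda=lam,
        channel_idx=(
            np.arange(F.shape[1]) if channel_idx is None else np.asarray(channel_idx)
        ),
    )


def ole_decode(
    model: EncodingModel, zrates: np.ndarray, gamma: Optional[float] = None
) -> np.ndarray:
    """Invert the stacked encoding model: dims x bins velocity estimates.

    v_hat = (B'B + gamma*I)^-1 B'(f - b0), with gamma defaulting to
    1e-6 * trace(B'B)/dims for numerical stability.
    """
    B = model.slopes
    if B.shape[0] < B.shape[1]:
        raise ValueError("need at least as many channels as decoded dims")
    G = B.T @ B
    if gamma is None:
        gamma = 1e-6 * np.trace(G) / G.shape[0]
    resid = np.asarray(zrates, dtype=float) - model.intercepts[:, None]
    return np.linalg.solve(G + gamma * np.eye(G.shape[0]), B.T @ resid)


class IndirectOLEDecoder(BaseEstimator, RegressorMixin):
    """scikit-learn wrapper: fit the encoding on (zrates, velocities) and
    predict velocities from z-rates by regularized inversion.

    ``fit`` takes X = bins x channels z-rates and y = bins x dims velocities;
    ``predict`` returns bins x dims.  ``lam`` is the ridge penalty of the
    encoding fit ('cv' selects it by 5-fold inner cross-validation over a
    log-spaced grid); ``gamma`` regularizes the inversion.
    """

    def __init__(self, lam: float | str = "cv", gamma: Optional[float] = None,
                 cv_splits: int = 5, random_state: int = 0):
        self.lam = lam
        self.gamma = gamma
        self.cv_splits = cv_splits
        self.random_state = random_state

    def _select_lambda(self, F: np.ndarray, V: np.ndarray) -> float:
        kf = KFold(self.cv_splits, shuffle=True, random_state=self.random_state)
        errs = np.zeros(len(LAMBDA_GRID))
        for train, test in kf.split(V):
            for i, lam in enumerate(LAMBDA_GRID):
                b0, B = _ridge_solve(V[train], F[train], lam)
                pred = b0[None] + V[test] @ B.T
                errs[i] += np.sum((F[test] - pred) ** 2)
        return float(LAMBDA_GRID[int(np.argmin(errs))])

    def fit(self, X: np.ndarray, y: np.ndarray):
        F = np.asarray(X, dtype=float)
        V = np.asarray(y, dtype=float)
        if V.ndim == 1:
            V = V[:, None]
        lam = self.lam
        if lam == "cv":
            lam = self._select_lambda(F, V)
        self.lambda_ = float(lam)
        self.model_ = fit_encoding(F.T, V.T, lam=self.lambda_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return ole_decode(self.model_, np.asarray(X, dtype=float).T, self.gamma).T


# ---------------------------------------------------------------------------
# session-level leave-one-trial-out evaluation


@dataclass
class DecodingPerformance:
    """Held-out decoding metrics for one session x array condition."""

    session_seed: int
    task: str
    condition: str
    translation_r2: float
    grasp_r2: float = np.nan
    click_accuracy: float = np.nan
    n_trials: int = 0


def squared_correlation(pred: np.ndarray, actual: np.ndarray) -> float:
    """Squared Pearson correlation; NaN when either side has no variance."""
    if np.std(pred) == 0 or np.std(actual) == 0:
        return np.nan
    return float(np.corrcoef(pred, actual)[0, 1] ** 2)


def _trial_of_bins(session: SessionBundle) -> np.ndarray:
    """Trial id per bin (-1 outside any trial)."""
    ids = np.full(session.n_bins, -1, dtype=int)
    for tr in session.trials.itertuples():
        b0 = int(round(tr.baseline_onset_s * session.bin_rate))
        b1 = int(round(tr.end_s * session.bin_rate))
        ids[b0:b1] = tr.trial_id
    return ids


def movement_mask(
    kin: pd.DataFrame,
    trial_ids: np.ndarray,
    phases: Sequence[str],
    dims: Sequence[str],
) -> np.ndarray:
    """Bins in the given phases whose speed exceeds 1% of the trial peak."""
    speed = np.linalg.norm(kin[list(dims)].to_numpy(), axis=1)
    in_phase = kin["phase_label"].isin(phases).to_numpy()
    mask = np.zeros(len(kin), dtype=bool)
    for tid in np.unique(trial_ids[trial_ids >= 0]):
        sel = (trial_ids == tid) & in_phase
        if not sel.any():
            continue
        peak = speed[sel].max()
        mask |= sel & (speed > SPEED_MASK_FRACTION * peak)
    return mask


def _loocv_predict(
    Z: np.ndarray,
    V: np.ndarray,
    trial_ids: np.ndarray,
    mask: np.ndarray,
    decoder: IndirectOLEDecoder,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-trial-out predictions over masked bins.

    Z: channels x bins, V: dims x bins.  Returns (pred, actual), dims x
    pooled masked bins of the held-out trials.
    """
    preds, actuals = [], []
    trials = np.unique(trial_ids[trial_ids >= 0])
    if trials.size < 2:
        raise ValueError("leave-one-trial-out needs >=2 trials")
    for tid in trials:
        test = mask & (trial_ids == tid)
        train = mask & (trial_ids != tid) & (trial_ids >= 0)
        if not test.any():
            continue
        dec = clone(decoder).fit(Z[:, train].T, V[:, train].T)
        preds.append(dec.predict(Z[:, test].T).T)
        actuals.append(V[:, test])
    return np.concatenate(preds, axis=1), np.concatenate(actuals, axis=1)


def loocv_decode(
    session: SessionBundle,
    condition: str = "both",
    smoothed: SmoothedRates | None = None,
    lam: float | str = "cv",
    gamma: Optional[float] = None,
) -> DecodingPerformance:
    """Leave-one-trial-out velocity decoding for one array condition.

    Virtual-arm sessions decode (vx, vy, vz) from reach/carry bins and vg
    from grasp/release bins with a separately fitted model; cursor sessions
    decode (vx, vy) from reach/carry bins.  ``translation_r2`` is the mean
    squared correlation over the translation dims on held-out movement bins.
    """
    if session.kinematics is None:
        raise ValueError("session has no kinematics to decode")
    if smoothed is None:
        smoothed = preprocess_session(session.counts)
    channels = session.channels_of(condition)
    channels = channels[smoothed.active[channels]]
    if channels.size < 4:
        raise ValueError("need at least 4 active channels to decode")
    Z = smoothed.zrates[channels]
    kin = session.kinematics
    trial_ids = _trial_of_bins(session)
    decoder = IndirectOLEDecoder(lam=lam, gamma=gamma)

    is_cursor = session.task.startswith("cursor")
    trans_dims = ("vx", "vy") if is_cursor else ("vx", "vy", "vz")
    Vt = kin[list(trans_dims)].to_numpy().T
    t_mask = movement_mask(kin, trial_ids, ("reach", "carry"), trans_dims)
    pred, actual = _loocv_predict(Z, Vt, trial_ids, t_mask, decoder)
    r2s = [squared_correlation(pred[d], actual[d]) for d in range(len(trans_dims))]
    r2s = [r for r in r2s if not np.isnan(r)]
    translation_r2 = float(np.mean(r2s)) if r2s else np.nan

    grasp_r2 = np.nan
    if not is_cursor:
        Vg = kin[["vg"]].to_numpy().T
        g_mask = movement_mask(kin, trial_ids, ("grasp", "release"), ("vg",))
        pred_g, actual_g = _loocv_predict(Z, Vg, trial_ids, g_mask, decoder)
        grasp_r2 = squared_correlation(pred_g[0], actual_g[0])

    return DecodingPerformance(
        session_seed=session.seed,
        task=session.task,
        condition=condition,
        translation_r2=translation_r2,
        grasp_r2=grasp_r2,
        n_trials=len(session.trials),
    )


# ---------------------------------------------------------------------------
# click-state HMM


def viterbi(
    log_start: np.ndarray, log_trans: np.ndarray, log_emis: np.ndarray
) -> np.ndarray:
    """Most likely state path; ``log_emis`` is bins x states."""
    n, k = log_emis.shape
    delta = log_start + log_emis[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + log_emis[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


class ClickHMMClassifier(BaseEstimator, ClassifierMixin):
    """Two-state (unclicked/clicked) HMM on a Fisher-discriminant projection.

    ``fit`` takes X = bins x channels z-rates and y = binary click labels:
    the projection is the linear discriminant between the two labeled
    states, emissions are state-conditional Gaussians on the projection,
    transitions are label bigram frequencies with add-one smoothing, and the
    start distribution is the label frequency.  ``predict`` runs Viterbi.
    """

    def __init__(self, var_floor: float = 1e-9, shrinkage: str | float = "auto"):
        self.var_floor = var_floor
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both click states must be present in training data")
        # shrinkage stabilizes the within-class covariance: smoothed rates are
        # temporally correlated, so the effective sample count is far below
        # the bin count
        self.lda_ = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage=self.shrinkage, n_components=1
        ).fit(X, y)
        s = self.lda_.transform(X)[:, 0]
        self.means_ = np.array([s[y == c].mean() for c in self.classes_])
        self.vars_ = np.maximum(
            np.array([s[y == c].var() for c in self.classes_]), self.var_floor
        )
        k = len(self.classes_)
        counts = np.zeros((k, k))
        for a, b in zip(y[:-1], y[1:]):
            counts[a, b] += 1
        self.transmat_ = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + k)
        self.startprob_ = np.bincount(y, minlength=k) / len(y)
        return self

    def _log_emission(self, X: np.ndarray) -> np.ndarray:
        s = self.lda_.transform(np.asarray(X, dtype=float))[:, 0]
        return -0.5 * (
            np.log(2 * np.pi * self.vars_[None])
            + (s[:, None] - self.means_[None]) ** 2 / self.vars_[None]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "transmat_")
        path = viterbi(
            np.log(self.startprob_ + 1e-300),
            np.log(self.transmat_),
            self._log_emission(X),
        )
        return self.classes_[path]


def click_epochs(click_state: np.ndarray) -> list[np.ndarray]:
    """Split bins into click-unclick epochs at click onsets.

    An epoch runs from one 0->1 transition to the next; leading unclicked
    bins are merged into the first epoch.  A session with no clicks is one
    epoch.
    """
    click_state = np.asarray(click_state).astype(int)
    onsets = np.flatnonzero(np.diff(click_state, prepend=0) == 1)
    bounds = [0] + [o for o in onsets.tolist() if o > 0] + [len(click_state)]
    return [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def loocv_click(
    session: SessionBundle,
    condition: str = "both",
    smoothed: SmoothedRates | None = None,
) -> DecodingPerformance:
    """Leave-one-epoch-out click-state decoding accuracy for one condition."""
    if session.kinematics is None or "click_state" not in session.kinematics:
        raise ValueError("session has no click labels")
    if smoothed is None:
        smoothed = preprocess_session(session.counts)
    channels = session.channels_of(condition)
    channels = channels[smoothed.active[channels]]
    Z = smoothed.zrates[channels].T  # bins x channels
    y = session.kinematics["click_state"].to_numpy().astype(int)
    epochs = click_epochs(y)
    if len(epochs) < 2:
        raise ValueError("need >=2 click-unclick epochs for leave-one-out")
    correct = total = 0
    for i, ep in enumerate(epochs):
        train = np.concatenate([e for j, e in enumerate(epochs) if j != i])
        clf = ClickHMMClassifier().fit(Z[train], y[train])
        pred = clf.predict(Z[ep])
        correct += int(np.sum(pred == y[ep]))
        total += len(ep)
    return DecodingPerformance(
        session_seed=session.seed,
        task=session.task,
        condition=condition,
        translation_r2=np.nan,
        click_accuracy=correct / total,
        n_trials=len(session.trials),
    )
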