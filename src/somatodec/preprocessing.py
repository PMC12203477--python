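"""Spike-count preprocessing: binning, exponential smoothing, z-scoring.

Binned multi-unit counts (50 Hz) are converted to firing rates by causal
convolution with a truncated exponential kernel (440 ms window by default)
and normalized per channel to z-scored rates.  The transformers follow the
scikit-learn estimator protocol and operate on channels x bins matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synthetic import BIN_RATE_HZ

#: channels whose rate variance falls below this (spikes/s)^2 are flagged
#: inactive and excluded from downstream analyses
VARIANCE_FLOOR = 1e-6


def bin_spikes(
    events: list[np.ndarray],
    duration_s: float,
    bin_rate: float = BIN_RATE_HZ,
) -> np.ndarray:
    """Bin per-channel spike times into a channels x bins count matrix.

    Bin k is the half-open interval [k/bin_rate, (k+1)/bin_rate); the number
    of columns is ceil(duration_s * bin_rate).
    """
    n_bins = int(np.ceil(duration_s * bin_rate))
    edges = np.arange(n_bins + 1) / bin_rate
    counts = np.zeros((len(events), n_bins), dtype=np.int64)
    for c, ev in enumerate(events):
        ev = np.asarray(ev, dtype=float)
        if ev.size == 0:
            continue
        if np.any(ev < 0):
            raise ValueError("spike times must be non-negative")
        if np.any(ev >= duration_s):
            raise ValueError("spike times must fall within [0, duration)")
        counts[c], _ = np.histogram(ev, bins=edges)
    return counts


def exponential_kernel(
    window_ms: float = 440.0, tau_ms: float | None = None, bin_rate: float = BIN_RATE_HZ
) -> np.ndarray:
    """Causal exponential kernel truncated at ``window_ms``, unit sum.

    k[j] = exp(-j * dt / tau) for j = 0 .. window/dt - 1.  The default decay
    constant is window/4 so the kernel falls to ~e^-4 across its support.
    """
    dt_ms = 1000.0 / bin_rate
    if window_ms < dt_ms:
        raise ValueError("smoothing window must cover at least one bin")
    if tau_ms is None:
        tau_ms = window_ms / 4.0
    j = np.arange(int(round(window_ms / dt_ms)))
    k = np.exp(-j * dt_ms / tau_ms)
    return k / k.sum()


class ExponentialSmoother(BaseEstimator, TransformerMixin):
    """Causal exponential-window rate estimator.

    ``transform`` converts a channels x bins count matrix to firing rates in
    spikes/s: counts are scaled by the bin rate and convolved (causally) with
    the truncated, unit-sum exponential kernel.

    Parameters
    ----------
    window_ms : kernel support in milliseconds (default 440).
    tau_ms : decay constant; default ``window_ms / 4``.
    bin_rate : sampling rate of the count bins in Hz.
    """

    def __init__(
        self,
        window_ms: float = 440.0,
        tau_ms: float | None = None,
        bin_rate: float = BIN_RATE_HZ,
    ):
        self.window_ms = window_ms
        self.tau_ms = tau_ms
        self.bin_rate = bin_rate

    def fit(self, X=None, y=None):
        self.kernel_ = exponential_kernel(self.window_ms, self.tau_ms, self.bin_rate)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "kernel_")
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        full = fftconvolve(X * self.bin_rate, self.kernel_[None, :], axes=1)
        return full[:, : X.shape[1]]


def smooth_rates(
    counts: np.ndarray,
    window_ms: float = 440.0,
    tau_ms: float | None = None,
    bin_rate: float = BIN_RATE_HZ,
) -> np.ndarray:
    """Functional wrapper over :class:`ExponentialSmoother`."""
    return ExponentialSmoother(window_ms, tau_ms, bin_rate).fit().transform(counts)


@dataclass
class SmoothedRates:
    """Smoothed and z-scored firing rates for one session.

    ``zrates = (rates - zmean[:, None]) / zsd[:, None]`` channel-wise;
    channels with near-zero variance over the normalization epoch are flagged
    in ``inactive`` (their zrates are set to 0) and are excluded downstream.
    """

    rates: np.ndarray
    zrates: np.ndarray
    zmean: np.ndarray
    zsd: np.ndarray
    inactive: np.ndarray

    @property
    def active(self) -> np.ndarray:
        return ~self.inactive


class ChannelZScorer(BaseEstimator, TransformerMixin):
    """Per-channel z-scoring over a normalization epoch.

    ``fit`` learns per-channel mean and standard deviation over the bins
    selected by ``epoch_mask`` (whole session when None); ``transform``
    applies them.  Channels with variance below ``variance_floor`` are
    flagged in ``inactive_`` and transformed to zeros.
    """

    def __init__(self, variance_floor: float = VARIANCE_FLOOR):
        self.variance_floor = variance_floor

    def fit(self, X: np.ndarray, y=None, epoch_mask: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if epoch_mask is None:
            epoch = X
        else:
            epoch_mask = np.asarray(epoch_mask, dtype=bool)
            if not epoch_mask.any():
                raise ValueError("normalization epoch mask selects no bins")
            epoch = X[:, epoch_mask]
        if epoch.shape[1] < 2:
            raise ValueError("need at least two bins to normalize")
        self.mean_ = epoch.mean(axis=1)
        var = epoch.var(axis=1, ddof=0)
        self.inactive_ = var < self.variance_floor
        self.scale_ = np.where(self.inactive_, 1.0, np.sqrt(var))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "scale_")
        Z = (np.asarray(X, dtype=float) - self.mean_[:, None]) / self.scale_[:, None]
        Z[self.inactive_] = 0.0
        return Z


def zscore(
    rates: np.ndarray,
    epoch_mask: np.ndarray | None = None,
    variance_floor: float = VARIANCE_FLOOR,
) -> SmoothedRates:
    """z-score smoothed rates per channel; see :class:`ChannelZScorer`."""
    scaler = ChannelZScorer(variance_floor).fit(rates, epoch_mask=epoch_mask)
    return SmoothedRates(
        rates=np.asarray(rates, dtype=float),
        zrates=scaler.transform(rates),
        zmean=scaler.mean_,
        zsd=scaler.scale_,
        inactive=scaler.inactive_,
    )


def preprocess_session(counts: np.ndarray, **smoother_kwargs) -> SmoothedRates:
    """counts -> smoothed rates -> whole-session z-scores, in one call."""
    return zscore(smooth_rates(counts, **smoother_kwargs))
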