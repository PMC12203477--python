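"""Per-channel movement tuning: response windows, significance, depth maps.

For each session and movement type the population response window is located
by PCA over trial-averaged z-scored rates (the first principal component is
a proxy for overall population activity; its peak magnitude defines the
window center t_M).  Tuning of each channel is then assessed by a two-tailed
one-sample t-test on per-trial spike-count differences between a 500 ms
Movement window centered on t_M and the 500 ms Baseline window immediately
preceding movement onset, Bonferroni-corrected across the four movement
types (per-test alpha 0.0125).  Depth of modulation is the trial-averaged
largest signed firing-rate excursion from baseline within the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .preprocessing import SmoothedRates, preprocess_session
from .synthetic import MOVEMENTS, SessionBundle


@dataclass(frozen=True)
class TuningTestConfig:
    """Family-wise error control for the per-channel tuning tests."""

    alpha_family: float = 0.05
    n_tests: int = len(MOVEMENTS)

    @property
    def alpha_per_test(self) -> float:
        return self.alpha_family / self.n_tests


@dataclass
class MovementWindow:
    """Response window of one movement type within a session.

    Times are seconds relative to Movement-phase onset.  ``window_bins`` is
    the half-open bin range [start, stop) relative to movement onset; its
    length is 25 bins (500 ms at 50 Hz) at defaults.
    """

    movement: str
    t_m_s: float
    window_bins: tuple[int, int]
    pc1_scores: np.ndarray = field(repr=False)
    rel_time_s: np.ndarray = field(repr=False)


def _trial_onset_bins(session: SessionBundle, movement: str) -> np.ndarray:
    trials = session.trials
    sel = trials[trials["movement_label"] == movement]
    if len(sel) < 2:
        raise ValueError(f"need >=2 trials of movement {movement!r}")
    return np.round(sel["movement_onset_s"].to_numpy() * session.bin_rate).astype(int)


def find_movement_window(
    session: SessionBundle,
    smoothed: SmoothedRates,
    movement: str,
    window_ms: float = 500.0,
    pre_onset_s: float = 0.5,
) -> MovementWindow:
    """Locate the 500 ms response window for one movement type.

    z-scored rates are averaged over the movement's trials on a grid aligned
    to Movement onset spanning [-pre_onset_s, trial end]; PCA (bins as
    observations, channels as variables) gives the PC1 score series, and t_M
    is the time of its peak magnitude within the Movement phase.  The window
    is centered on t_M and shifted, if necessary, to lie inside the phase.
    """
    onset_bins = _trial_onset_bins(session, movement)
    trials = session.trials
    sel = trials[trials["movement_label"] == movement]
    active = np.flatnonzero(smoothed.active)
    if active.size < 1:
        raise ValueError("all channels inactive")

    pre_bins = int(round(pre_onset_s * session.bin_rate))
    trial_len_s = (sel["end_s"] - sel["movement_onset_s"]).min()
    post_bins = int(np.floor(trial_len_s * session.bin_rate))
    rel = np.arange(-pre_bins, post_bins)

    Z = smoothed.zrates[active]
    segs = np.stack([Z[:, b - pre_bins : b + post_bins] for b in onset_bins])
    avg = segs.mean(axis=0).T  # bins x channels

    if avg.shape[1] == 1:
        scores = avg[:, 0] - avg[:, 0].mean()
    else:
        pca = PCA(n_components=1)
        scores = pca.fit_transform(avg)[:, 0]

    move_dur_s = (sel["rest_onset_s"] - sel["movement_onset_s"]).min()
    move_bins = int(round(move_dur_s * session.bin_rate))
    in_phase = (rel >= 0) & (rel < move_bins)
    phase_scores = np.where(in_phase, np.abs(scores), -np.inf)
    peak = int(np.argmax(phase_scores))
    t_m_bin = rel[peak]

    win_len = int(round(window_ms / 1000.0 * session.bin_rate))
    start = t_m_bin - win_len // 2
    start = int(np.clip(start, 0, max(move_bins - win_len, 0)))
    return MovementWindow(
        movement=movement,
        t_m_s=t_m_bin / session.bin_rate,
        window_bins=(start, start + win_len),
        pc1_scores=scores,
        rel_time_s=rel / session.bin_rate,
    )


def trial_deltas(
    session: SessionBundle, window: MovementWindow, movement: str | None = None
) -> np.ndarray:
    """Per-trial raw spike-count differences, Movement window minus Baseline.

    The Baseline window is the 500 ms (same length as the Movement window)
    immediately before Movement onset.  Returns a channels x trials integer
    array of signed count differences.
    """
    movement = window.movement if movement is None else movement
    onset_bins = _trial_onset_bins(session, movement)
    start, stop = window.window_bins
    win_len = stop - start
    counts = session.counts
    if onset_bins.min() - win_len < 0 or onset_bins.max() + stop > session.n_bins:
        raise ValueError("analysis window exceeds the recording extent")
    deltas = np.empty((counts.shape[0], onset_bins.size), dtype=np.int64)
    for i, b in enumerate(onset_bins):
        move = counts[:, b + start : b + stop].sum(axis=1)
        base = counts[:, b - win_len : b].sum(axis=1)
        deltas[:, i] = move - base
    return deltas


def test_tuning(
    deltas: np.ndarray, config: TuningTestConfig = TuningTestConfig()
) -> pd.DataFrame:
    """Two-tailed one-sample t-test of count differences against zero.

    ``deltas`` is 1-D (one channel) or channels x trials.  Zero-variance
    samples are degenerate: t = 0, p = 1, never significant.  Significance
    uses the Bonferroni per-test threshold from ``config``.
    """
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    if deltas.shape[1] < 2:
        raise ValueError("need >=2 trials for the tuning test")
    degenerate = deltas.var(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_1samp(deltas, 0.0, axis=1)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "significant": p < config.alpha_per_test,
            "degenerate": degenerate,
            "mean_delta_counts": deltas.mean(axis=1),
        }
    )


def depth_of_modulation(
    session: SessionBundle, smoothed: SmoothedRates, window: MovementWindow
) -> np.ndarray:
    """Signed depth of modulation (spikes/s) per channel.

    Per trial, the smoothed-rate series in the Movement window minus that
    trial's mean Baseline-window rate; the excursion of largest magnitude is
    retained with its sign and averaged across trials.
    """
    onset_bins = _trial_onset_bins(session, window.movement)
    start, stop = window.window_bins
    win_len = stop - start
    rates = smoothed.rates
    per_trial = np.empty((rates.shape[0], onset_bins.size))
    for i, b in enumerate(onset_bins):
        base = rates[:, b - win_len : b].mean(axis=1)
        excur = rates[:, b + start : b + stop] - base[:, None]
        idx = np.argmax(np.abs(excur), axis=1)
        per_trial[:, i] = excur[np.arange(excur.shape[0]), idx]
    return per_trial.mean(axis=1)


def map_session(
    session: SessionBundle,
    smoothed: SmoothedRates | None = None,
    config: TuningTestConfig = TuningTestConfig(),
    window_ms: float = 500.0,
) -> tuple[pd.DataFrame, dict[str, MovementWindow]]:
    """Run the full tuning analysis for every movement type of a session.

    Returns a tidy results table (one row per channel x movement) and the
    per-movement response windows.
    """
    if smoothed is None:
        smoothed = preprocess_session(session.counts)
    frames = []
    windows: dict[str, MovementWindow] = {}
    for mv in MOVEMENTS:
        win = find_movement_window(session, smoothed, mv, window_ms=window_ms)
        windows[mv] = win
        res = test_tuning(trial_deltas(session, win), config)
        res.insert(0, "movement", mv)
        res.insert(0, "channel_id", session.array_map["channel_id"].to_numpy())
        res.insert(1, "array_id", session.array_map["array_id"].to_numpy())
        res["depth_of_modulation"] = depth_of_modulation(session, smoothed, win)
        res.loc[~smoothed.active, "significant"] = False
        frames.append(res)
    return pd.concat(frames, ignore_index=True), windows


def proportions_by_array(results: pd.DataFrame) -> pd.DataFrame:
    """Per array, channels tuned to each movement among channels tuned to any.

    The denominator is the number of channels on the array significant for at
    least one movement, so proportions across movements may sum above 1.
    Arrays with no modulated channel report NaN.
    """
    rows = []
    for array_id, grp in results.groupby("array_id", sort=False):
        any_sig = grp.groupby("channel_id")["significant"].any()
        denom = int(any_sig.sum())
        for mv in MOVEMENTS:
            num = int(grp.loc[(grp["movement"] == mv) & grp["significant"],
                              "channel_id"].nunique())
            rows.append(
                {
                    "array_id": array_id,
                    "movement": mv,
                    "n_tuned": num,
                    "n_modulated": denom,
                    "proportion": num / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)


def depth_heatmap(
    results: pd.DataFrame, array_map: pd.DataFrame, movement: str, array_id: str
) -> np.ndarray:
    """10 x 10 grid of signed modulation depth for one array and movement.

    Each channel lands at its unique (grid_row, grid_col); unoccupied
    electrodes are NaN.  Used by the figure export.
    """
    from .synthetic import GRID_SIZE

    grid = np.full((GRID_SIZE, GRID_SIZE), np.nan)
    sel = results[(results["movement"] == movement) & (results["array_id"] == array_id)]
    merged = sel.merge(array_map, on=["channel_id", "array_id"])
    grid[merged["grid_row"].to_numpy(), merged["grid_col"].to_numpy()] = (
        merged["depth_of_modulation"].to_numpy()
    )
    return grid


def plot_depth_maps(results: pd.DataFrame, array_map: pd.DataFrame, path=None):
    """Array x movement grid of depth heatmaps with significance dots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arrays = list(dict.fromkeys(array_map["array_id"]))
    fig, axes = plt.subplots(
        len(arrays), len(MOVEMENTS), figsize=(3 * len(MOVEMENTS), 3 * len(arrays)),
        squeeze=False,
    )
    vmax = max(np.abs(results["depth_of_modulation"]).max(), 1e-9)
    for i, arr in enumerate(arrays):
        for j, mv in enumerate(MOVEMENTS):
            ax = axes[i][j]
            grid = depth_heatmap(results, array_map, mv, arr)
            im = ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            sel = results[
                (results["movement"] == mv)
                & (results["array_id"] == arr)
                & results["significant"]
            ].merge(array_map, on=["channel_id", "array_id"])
            ax.scatter(sel["grid_col"], sel["grid_row"], s=6, c="k")
            ax.set_title(f"{arr} / {mv}", fontsize=9)
            ax.set_xticks([]); ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.7, label="depth of modulation (spikes/s)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
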