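"""Seeded synthetic motor-cortex populations and task sessions.

The generator produces multi-unit channel populations on two simulated
microelectrode arrays (a medial and a lateral grid on the precentral gyrus)
and the three task-session types the analysis pipeline consumes:

* somatotopy mapping (blocked attempted movements: grasp, wrist, elbow,
  shoulder),
* virtual arm-and-hand reach/grasp observation (3-D translation + 1-D grasp
  velocity encoding),
* 2-D cursor center-out click-and-drag (abstract or wrist imagery).

Each channel carries ground-truth tuning parameters so downstream analyses
can be validated by parameter recovery.  Per-movement modulation depth
follows a mediolateral gradient: proximal movements (elbow, shoulder) are
represented more strongly medially, distal movements (grasp, wrist) more
strongly laterally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

BIN_RATE_HZ = 50.0
BIN_DT = 1.0 / BIN_RATE_HZ

#: Canonical movement order (also the classifier tie-break order).
MOVEMENTS = ("grasp", "wrist", "elbow", "shoulder")
#: Movements represented more strongly on the lateral (hand-area) array.
DISTAL_MOVEMENTS = ("grasp", "wrist")
#: Movements represented more strongly on the medial (arm-area) array.
PROXIMAL_MOVEMENTS = ("elbow", "shoulder")

ARRAYS = ("lateral", "medial")
GRID_SIZE = 10  # 10 x 10 electrode grid per array


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic population / session generator.

    Durations are seconds, rates spikes/s, velocities in workspace units/s.
    """

    n_channels_per_array: int = 96
    seed: int = 0

    # --- tuning gradient -------------------------------------------------
    #: scales how strongly expected |depth| varies with mediolateral position
    gradient_slope: float = 1.0
    #: expected |depth| of a tuned channel at its least-preferred position
    depth_base: float = 4.0
    #: additional expected |depth| at the most-preferred position (per unit slope)
    depth_span: float = 12.0
    #: lognormal spread of per-channel depth magnitudes around the expectation
    depth_cv: float = 0.3
    #: fraction of channels with no movement tuning at all
    untuned_fraction: float = 0.5

    # --- baseline firing -------------------------------------------------
    baseline_rate_mean: float = 15.0
    baseline_rate_sd: float = 5.0
    baseline_rate_floor: float = 1.0

    # --- somatotopy task -------------------------------------------------
    #: (Baseline, Movement, Rest) phase durations
    phase_durations_s: tuple[float, float, float] = (3.0, 3.0, 2.0)
    n_blocks: int = 20

    # --- velocity encoding ----------------------------------------------
    #: SD of each translation coefficient at full proximal weighting (z-units
    #: per workspace-unit/s)
    enc_trans_sd: float = 0.35
    #: SD of the grasp coefficient at full distal weighting
    enc_grasp_sd: float = 0.15
    #: SD of the per-channel intercept (z-units)
    enc_b0_sd: float = 0.1
    #: floor of the mediolateral weighting (untargeted side keeps this much)
    enc_weight_floor: float = 0.35
    #: per-bin Gaussian noise on the z-scale drive, applied to every channel
    noise_scale: float = 1.0
    #: spikes/s per z-unit when converting the z-scale drive back to a rate
    rate_sd: float = 10.0

    # --- reach & grasp (virtual arm) task --------------------------------
    n_reach_trials: int = 30  # typical calibration sessions hold 18-36
    target_distance: float = 1.0
    reach_duration_s: float = 1.2
    grasp_duration_s: float = 0.6
    carry_duration_s: float = 1.2
    release_duration_s: float = 0.6
    intertrial_s: float = 0.5

    # --- cursor task ------------------------------------------------------
    n_cursor_trials: int = 40
    cursor_reach_s: float = 1.2
    cursor_hold_s: float = 0.8
    #: click-unclick epochs per session; None draws 12 or 13 at random
    n_click_epochs: Optional[int] = None
    #: sustained z-scale drive per unit grasp coefficient while click is held
    click_hold_scale: float = 2.0
    click_pulse_s: float = 0.3

    poisson: bool = True

    def validate(self) -> None:
        if self.n_channels_per_array <= 0:
            raise ValueError("n_channels_per_array must be positive")
        if self.n_channels_per_array > GRID_SIZE * GRID_SIZE:
            raise ValueError("more channels than electrodes on a 10x10 grid")
        if any(d <= 0 for d in self.phase_durations_s):
            raise ValueError("phase durations must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.untuned_fraction <= 1.0:
            raise ValueError("untuned_fraction must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass
class SessionBundle:
    """One synthetic recording session on the common 50 Hz grid.

    ``counts`` rows follow ``array_map`` row order.  ``true_rates`` (spikes/s,
    pre-Poisson) and ``true_z`` (pre-noise z-scale encoding drive) are
    generator ground truth kept for validation; they are not part of the
    on-disk layout contract.
    """

    counts: np.ndarray
    trials: pd.DataFrame
    array_map: pd.DataFrame
    kinematics: Optional[pd.DataFrame] = None
    bin_rate: float = BIN_RATE_HZ
    seed: int = 0
    task: str = ""
    meta: dict = field(default_factory=dict)
    true_rates: Optional[np.ndarray] = None
    true_z: Optional[np.ndarray] = None

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins / self.bin_rate

    def channels_of(self, condition: str) -> np.ndarray:
        """Row indices for an array condition: 'both', 'medial' or 'lateral'."""
        if condition == "both":
            return np.arange(self.n_channels)
        if condition not in ARRAYS:
            raise ValueError(f"unknown array condition: {condition!r}")
        return np.flatnonzero(self.array_map["array_id"].to_numpy() == condition)


# ---------------------------------------------------------------------------
# population


def expected_depth_magnitude(
    pos: np.ndarray | float, movement: str, config: GeneratorConfig
) -> np.ndarray | float:
    """Expected |depth| (spikes/s) of a *tuned* channel at mediolateral
    position ``pos`` (0 = most lateral, 1 = most medial)."""
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement: {movement!r}")
    pos = np.asarray(pos, dtype=float)
    x = pos if movement in PROXIMAL_MOVEMENTS else 1.0 - pos
    return config.depth_base + config.gradient_slope * config.depth_span * x


def _grid_positions(n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    return idx // GRID_SIZE, idx % GRID_SIZE


def make_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a ground-truth channel population.

    Returns one row per channel with array/grid position, mediolateral
    position, baseline rate, signed per-movement modulation depths, and the
    velocity-encoding coefficients (b0, bx, by, bz, bg) plus the
    distal-weighted 2-D coefficients used for wrist-imagery cursor control.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_channels_per_array
    rows = []
    for array_id in ARRAYS:
        grid_row, grid_col = _grid_positions(n)
        # each array spans 0.4 of the mediolateral axis; within-array spread
        # follows the grid column so single-array maps show the gradient too
        frac = grid_col / (GRID_SIZE - 1)
        pos = 0.4 * frac if array_id == "lateral" else 0.6 + 0.4 * frac
        rows.append(
            pd.DataFrame(
                {
                    "array_id": array_id,
                    "grid_row": grid_row,
                    "grid_col": grid_col,
                    "mediolateral_pos": pos,
                }
            )
        )
    pop = pd.concat(rows, ignore_index=True)
    pop.insert(0, "channel_id", np.arange(len(pop)))

    n_total = len(pop)
    baseline = rng.normal(config.baseline_rate_mean, config.baseline_rate_sd, n_total)
    pop["baseline_rate"] = np.maximum(baseline, config.baseline_rate_floor)

    n_untuned = int(round(config.untuned_fraction * n_total))
    untuned = np.zeros(n_total, dtype=bool)
    untuned[rng.permutation(n_total)[:n_untuned]] = True
    pop["tuned"] = ~untuned

    sigma = config.depth_cv
    for mv in MOVEMENTS:
        mean_mag = expected_depth_magnitude(
            pop["mediolateral_pos"].to_numpy(), mv, config
        )
        # lognormal with unit mean so E[|depth|] matches expected_depth_magnitude
        mag = mean_mag * rng.lognormal(-0.5 * sigma**2, sigma, n_total)
        sign = rng.choice([-1.0, 1.0], n_total)
        depth = np.where(untuned, 0.0, sign * mag)
        pop[f"depth_{mv}"] = depth

    pos = pop["mediolateral_pos"].to_numpy()
    w0 = config.enc_weight_floor
    w_prox = w0 + (1 - w0) * pos
    w_dist = w0 + (1 - w0) * (1 - pos)
    pop["enc_b0"] = rng.normal(0.0, config.enc_b0_sd, n_total)
    for coef in ("bx", "by", "bz"):
        pop[f"enc_{coef}"] = rng.normal(0.0, config.enc_trans_sd * w_prox)
    pop["enc_bg"] = rng.normal(0.0, config.enc_grasp_sd * w_dist)
    for coef in ("bx", "by"):
        pop[f"wrist_{coef}"] = rng.normal(0.0, config.enc_trans_sd * w_dist)
    pop["noise_scale"] = config.noise_scale
    return pop


def _array_map(pop: pd.DataFrame) -> pd.DataFrame:
    return pop[
        ["channel_id", "array_id", "grid_row", "grid_col", "mediolateral_pos"]
    ].copy()


# ---------------------------------------------------------------------------
# kinematic primitives


def minimum_jerk_velocity(t: np.ndarray, duration: float, distance: float) -> np.ndarray:
    """Speed profile of a minimum-jerk point-to-point movement.

    Peak speed is 1.875 * distance / duration at the movement midpoint; the
    profile integrates to ``distance`` over ``[0, duration]``.
    """
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    return distance / duration * 30.0 * (tau**2 - 2 * tau**3 + tau**4)


def _rate_to_counts(
    rate_hz: np.ndarray, rng: np.random.Generator, poisson: bool
) -> np.ndarray:
    lam = np.maximum(rate_hz, 0.0) * BIN_DT
    if poisson:
        return rng.poisson(lam).astype(np.int64)
    # deterministic rounding that conserves the cumulative expected count
    cum = np.floor(np.cumsum(lam, axis=1) + 1e-9)
    return np.diff(np.concatenate([np.zeros((lam.shape[0], 1)), cum], axis=1)).astype(
        np.int64
    )


def spike_events_from_counts(
    counts: np.ndarray, bin_rate: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Materialize per-channel spike times uniformly within each bin."""
    events = []
    for row in counts:
        ks = np.repeat(np.arange(row.size), row)
        events.append(np.sort((ks + rng.random(ks.size)) / bin_rate))
    return events


# ---------------------------------------------------------------------------
# somatotopy mapping task


def simulate_somatotopy_session(
    pop: pd.DataFrame, config: GeneratorConfig, seed: Optional[int] = None
) -> SessionBundle:
    """Blocked attempted-movement session: 4 movements x n_blocks trials.

    During a trial's Movement phase each channel fires at
    ``baseline + depth[movement] * w(t)`` where w is a raised-cosine bump
    (0 at the phase edges, 1 at its center); elsewhere at baseline.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    b_dur, m_dur, r_dur = config.phase_durations_s
    trial_dur = b_dur + m_dur + r_dur
    order = np.concatenate(
        [rng.permutation(len(MOVEMENTS)) for _ in range(config.n_blocks)]
    )
    labels = [MOVEMENTS[i] for i in order]
    n_trials = len(labels)

    starts = np.arange(n_trials) * trial_dur
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "movement_label": labels,
            "baseline_onset_s": starts,
            "movement_onset_s": starts + b_dur,
            "rest_onset_s": starts + b_dur + m_dur,
            "end_s": starts + trial_dur,
        }
    )

    n_bins = int(round(n_trials * trial_dur * BIN_RATE_HZ))
    t = (np.arange(n_bins) + 0.5) * BIN_DT
    baseline = pop["baseline_rate"].to_numpy()[:, None]
    rates = np.broadcast_to(baseline, (len(pop), n_bins)).copy()

    depth_cols = {mv: pop[f"depth_{mv}"].to_numpy() for mv in MOVEMENTS}
    for tr in trials.itertuples():
        mv = tr.movement_label
        if mv not in depth_cols:
            raise ValueError(f"unknown movement label: {mv!r}")
        in_phase = (t >= tr.movement_onset_s) & (t < tr.rest_onset_s)
        u = (t[in_phase] - tr.movement_onset_s) / m_dur
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        rates[:, in_phase] = baseline + depth_cols[mv][:, None] * w[None, :]

    counts = _rate_to_counts(rates, rng, config.poisson)
    return SessionBundle(
        counts=counts,
        trials=trials,
        array_map=_array_map(pop),
        kinematics=None,
        seed=seed,
        task="somatotopy",
        meta={"phase_durations_s": list(config.phase_durations_s)},
        true_rates=rates,
    )


# ---------------------------------------------------------------------------
# encoding-driven sessions


_ENC_COLS = ["enc_b0", "enc_bx", "enc_by", "enc_bz", "enc_bg"]


def _encode_rates(
    pop: pd.DataFrame,
    V: np.ndarray,
    coef_cols: list[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """z-drive F = b0 + B @ V plus noise; returns (pre-noise z, rates)."""
    missing = [c for c in coef_cols if c not in pop.columns]
    if missing:
        raise ValueError(f"population lacks encoding coefficients: {missing}")
    b0 = pop[coef_cols[0]].to_numpy()[:, None]
    B = pop[coef_cols[1:]].to_numpy()
    z_true = b0 + B @ V
    noise = pop["noise_scale"].to_numpy()[:, None]
    z = z_true + noise * rng.standard_normal(z_true.shape)
    baseline = pop["baseline_rate"].to_numpy()[:, None]
    rates = np.maximum(baseline + config.rate_sd * z, 0.0)
    return z_true, rates


def simulate_reach_grasp_session(
    pop: pd.DataFrame, config: GeneratorConfig, seed: Optional[int] = None
) -> SessionBundle:
    """Virtual arm-and-hand observation session.

    Each trial: idle, minimum-jerk 3-D reach, grasp close, carry to a new
    target, grasp release.  Channel z-scale drive follows
    f = b0 + bx vx + by vy + bz vz + bg vg plus Gaussian noise, converted to
    non-negative rates (baseline + rate_sd * z) before Poisson draws.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    seg_plan = [
        ("idle", config.intertrial_s),
        ("reach", config.reach_duration_s),
        ("grasp", config.grasp_duration_s),
        ("carry", config.carry_duration_s),
        ("release", config.release_duration_s),
    ]
    n_trials = config.n_reach_trials
    if not 1 <= n_trials:
        raise ValueError("n_reach_trials must be >= 1")

    vx, vy, vz, vg, phase = [], [], [], [], []
    trial_rows = []
    t_cursor = 0.0
    for tr in range(n_trials):
        t0 = t_cursor
        onsets = {}
        for name, dur in seg_plan:
            n_seg = int(round(dur * BIN_RATE_HZ))
            ts = (np.arange(n_seg) + 0.5) * BIN_DT
            onsets[name] = t_cursor
            if name in ("reach", "carry"):
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                speed = minimum_jerk_velocity(ts, dur, config.target_distance)
                v3 = direction[:, None] * speed[None, :]
                vx.append(v3[0]); vy.append(v3[1]); vz.append(v3[2])
                vg.append(np.zeros(n_seg))
            elif name in ("grasp", "release"):
                sign = -1.0 if name == "grasp" else 1.0
                vg.append(sign * minimum_jerk_velocity(ts, dur, 1.0))
                vx.append(np.zeros(n_seg)); vy.append(np.zeros(n_seg))
                vz.append(np.zeros(n_seg))
            else:
                for buf in (vx, vy, vz, vg):
                    buf.append(np.zeros(n_seg))
            phase.append(np.repeat(name, n_seg))
            t_cursor += n_seg * BIN_DT
        trial_rows.append(
            {
                "trial_id": tr,
                "movement_label": "reach_grasp",
                "baseline_onset_s": t0,
                "movement_onset_s": onsets["reach"],
                "rest_onset_s": t_cursor,
                "end_s": t_cursor,
            }
        )

    V = np.vstack(
        [np.concatenate(vx), np.concatenate(vy), np.concatenate(vz), np.concatenate(vg)]
    )
    n_bins = V.shape[1]
    kin = pd.DataFrame(
        {
            "time_s": np.arange(n_bins) / BIN_RATE_HZ,
            "vx": V[0], "vy": V[1], "vz": V[2], "vg": V[3],
            "phase_label": np.concatenate(phase),
            "click_state": np.zeros(n_bins, dtype=int),
        }
    )
    z_true, rates = _encode_rates(pop, V, _ENC_COLS, config, rng)
    counts = _rate_to_counts(rates, rng, config.poisson)
    return SessionBundle(
        counts=counts,
        trials=pd.DataFrame(trial_rows),
        array_map=_array_map(pop),
        kinematics=kin,
        seed=seed,
        task="reach_grasp",
        true_rates=rates,
        true_z=z_true,
    )


def simulate_cursor_session(
    pop: pd.DataFrame,
    config: GeneratorConfig,
    imagery: str = "abstract",
    seed: Optional[int] = None,
) -> SessionBundle:
    """2-D center-out click-and-drag session.

    The cursor reaches one of 8 equally spaced peripheral targets, holds,
    and returns.  On click trials the click is pressed at target arrival and
    held through the drag back to center, released at the next target
    arrival, giving ``n_click_epochs`` click-unclick epochs per session
    (12 or 13 by default).  ``imagery`` selects the coefficient set that
    drives translation tuning: 'abstract' uses the proximal-weighted
    (bx, by) set, 'wrist' the distal-weighted wrist set.  Click information
    is carried entirely by the grasp coefficient bg: a transient grasp
    velocity at press/release and a sustained bg * click_hold_scale drive
    while the click is held.
    """
    config.validate()
    if imagery == "abstract":
        coef_cols = ["enc_b0", "enc_bx", "enc_by"]
    elif imagery == "wrist":
        coef_cols = ["enc_b0", "wrist_bx", "wrist_by"]
    else:
        raise ValueError(f"imagery must be 'abstract' or 'wrist', got {imagery!r}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n_trials = config.n_cursor_trials
    n_epochs = config.n_click_epochs
    if n_epochs is None:
        n_epochs = int(rng.integers(12, 14))
    if n_epochs * 2 > n_trials:
        raise ValueError("need at least two trials per click epoch")
    # click trials evenly spaced; click held from this trial's target arrival
    # to the next trial's target arrival
    click_trials = set(
        np.round(np.linspace(0, n_trials - 2, n_epochs)).astype(int).tolist()
    )

    angles = 2 * np.pi * np.arange(8) / 8
    targets = np.stack([np.cos(angles), np.sin(angles)], axis=1)

    seg_plan = [
        ("idle", config.intertrial_s),
        ("reach", config.cursor_reach_s),
        ("hold", config.cursor_hold_s),
        ("carry", config.cursor_reach_s),
    ]
    vx, vy, vg, phase, click = [], [], [], [], []
    trial_rows = []
    t_cursor = 0.0
    clicked = False
    n_pulse = int(round(config.click_pulse_s * BIN_RATE_HZ))
    pulse_ts = (np.arange(n_pulse) + 0.5) * BIN_DT
    pulse = minimum_jerk_velocity(pulse_ts, config.click_pulse_s, 1.0)

    for tr in range(n_trials):
        t0 = t_cursor
        direction = targets[int(rng.integers(8))]
        onsets = {}
        for name, dur in seg_plan:
            n_seg = int(round(dur * BIN_RATE_HZ))
            ts = (np.arange(n_seg) + 0.5) * BIN_DT
            onsets[name] = t_cursor
            seg_vg = np.zeros(n_seg)
            if name in ("reach", "carry"):
                sgn = 1.0 if name == "reach" else -1.0
                speed = minimum_jerk_velocity(ts, dur, config.target_distance)
                vx.append(sgn * direction[0] * speed)
                vy.append(sgn * direction[1] * speed)
            else:
                vx.append(np.zeros(n_seg)); vy.append(np.zeros(n_seg))
            if name == "hold":
                # click state toggles at target arrival
                if tr in click_trials and not clicked:
                    clicked = True
                    seg_vg[:n_pulse] = -pulse[: n_seg]
                elif clicked:
                    clicked = False
                    seg_vg[:n_pulse] = pulse[: n_seg]
            vg.append(seg_vg)
            click.append(np.repeat(int(clicked), n_seg))
            phase.append(np.repeat(name, n_seg))
            t_cursor += n_seg * BIN_DT
        trial_rows.append(
            {
                "trial_id": tr,
                "movement_label": "cursor",
                "baseline_onset_s": t0,
                "movement_onset_s": onsets["reach"],
                "rest_onset_s": t_cursor,
                "end_s": t_cursor,
            }
        )
    # release a click still held at session end is left open: last epoch ends
    # with the session (mirrors a final held drag)

    V2 = np.vstack([np.concatenate(vx), np.concatenate(vy)])
    vg_all = np.concatenate(vg)
    click_all = np.concatenate(click)
    n_bins = V2.shape[1]
    kin = pd.DataFrame(
        {
            "time_s": np.arange(n_bins) / BIN_RATE_HZ,
            "vx": V2[0], "vy": V2[1],
            "vz": np.zeros(n_bins), "vg": vg_all,
            "phase_label": np.concatenate(phase),
            "click_state": click_all,
        }
    )
    # drive: translation via the imagery coefficient set; click via bg
    # (transient grasp velocity + sustained hold term)
    grasp_drive = vg_all + config.click_hold_scale * click_all
    V_drive = np.vstack([V2, grasp_drive])
    z_true, rates = _encode_rates(
        pop, V_drive, coef_cols + ["enc_bg"], config, rng
    )
    counts = _rate_to_counts(rates, rng, config.poisson)
    return SessionBundle(
        counts=counts,
        trials=pd.DataFrame(trial_rows),
        array_map=_array_map(pop),
        kinematics=kin,
        seed=seed,
        task=f"cursor_{imagery}",
        meta={"imagery": imagery, "n_click_epochs": int(n_epochs)},
        true_rates=rates,
        true_z=z_true,
    )


def null_population(config: GeneratorConfig) -> pd.DataFrame:
    """Population with every movement depth zero (no movement information)."""
    pop = make_population(config)
    for mv in MOVEMENTS:
        pop[f"depth_{mv}"] = 0.0
    pop["tuned"] = False
    return pop


def zero_grasp_population(config: GeneratorConfig) -> pd.DataFrame:
    """Population with all grasp-related drive removed (no click information)."""
    pop = make_population(config)
    pop["enc_bg"] = 0.0
    pop["depth_grasp"] = 0.0
    return pop
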