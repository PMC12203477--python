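"""Response-window location, tuning tests and depth of modulation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_manual_session
from somatodec import (
    MOVEMENTS,
    GeneratorConfig,
    make_population,
    preprocess_session,
    proportions_by_array,
    trial_deltas,
)
from somatodec import test_tuning as tuning_test
from somatodec.preprocessing import SmoothedRates
from somatodec.somatotopy import (
    TuningTestConfig,
    depth_heatmap,
    depth_of_modulation,
    find_movement_window,
    map_session,
)
from somatodec.synthetic import simulate_somatotopy_session


def fabricate_smoothed(rates: np.ndarray) -> SmoothedRates:
    sd = rates.std(axis=1)
    sd[sd == 0] = 1.0
    z = (rates - rates.mean(axis=1, keepdims=True)) / sd[:, None]
    return SmoothedRates(
        rates=rates,
        zrates=z,
        zmean=rates.mean(axis=1),
        zsd=sd,
        inactive=rates.std(axis=1) == 0,
    )


@pytest.fixture(scope="module")
def bump_session():
    """Noiseless single-movement session with a bump peaking 1.5 s after
    movement onset (depth +12 on every channel)."""
    cfg = GeneratorConfig(n_channels_per_array=8, n_blocks=3, seed=4,
                          poisson=False, untuned_fraction=0.0)
    pop = make_population(cfg)
    for mv in MOVEMENTS:
        pop[f"depth_{mv}"] = 12.0
    return simulate_somatotopy_session(pop, cfg), pop


class TestMovementWindow:
    def test_window_is_25_bins(self, somatotopy_session, somatotopy_smoothed):
        win = find_movement_window(somatotopy_session, somatotopy_smoothed, "grasp")
        start, stop = win.window_bins
        assert stop - start == 25

    def test_window_inside_movement_phase(self, somatotopy_session, somatotopy_smoothed):
        for mv in MOVEMENTS:
            win = find_movement_window(somatotopy_session, somatotopy_smoothed, mv)
            start, stop = win.window_bins
            move_bins = int(round(3.0 * 50))
            assert 0 <= start and stop <= move_bins

    def test_noiseless_bump_peak_recovered(self, bump_session):
        session, _ = bump_session
        sm = preprocess_session(session.counts)
        win = find_movement_window(session, sm, "grasp")
        # raised-cosine bump peaks at the 3 s phase center; the causal
        # exponential kernel delays the smoothed peak by up to ~0.1 s
        assert abs(win.t_m_s - 1.5) <= 0.15

    def test_single_channel_uses_its_own_peak(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.2, (1, 2000))
        session = make_manual_session(counts, [3.0, 11.0, 19.0, 27.0])
        rates = np.zeros((1, 2000))
        # every trial peaks 1.1-1.3 s after movement onset
        for onset in (150, 550, 950, 1350):
            rates[0, onset + 55 : onset + 65] = 30.0
        sm = fabricate_smoothed(rates)
        win = find_movement_window(session, sm, "grasp")
        assert abs(win.t_m_s - 1.2) <= 0.1

    def test_all_inactive_channels_rejected(self, somatotopy_session):
        flat = fabricate_smoothed(np.ones_like(somatotopy_session.counts, dtype=float))
        with pytest.raises(ValueError, match="inactive"):
            find_movement_window(somatotopy_session, flat, "grasp")


class TestTrialDeltas:
    def test_identical_windows_give_zero(self):
        counts = np.ones((2, 2000), dtype=int)
        session = make_manual_session(counts, [3.0, 11.0])
        from somatodec.somatotopy import MovementWindow

        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        deltas = trial_deltas(session, window)
        assert np.all(deltas == 0)

    def test_rate_step_delta_matches_integral(self):
        """Baseline 10 spikes/s stepping to 30 in the movement phase gives a
        delta of (30-10) * 0.5 s = 10 counts per trial."""
        from somatodec.somatotopy import MovementWindow

        n_bins = 2000
        rates = np.full((1, n_bins), 10.0)
        onsets = [3.0, 11.0, 19.0, 27.0]
        for onset in onsets:
            b = int(onset * 50)
            rates[0, b : b + 150] = 30.0
        # deterministic counts: cumulative rounding conserves the integral
        lam = rates / 50.0
        cum = np.floor(np.cumsum(lam, axis=1) + 1e-9)
        counts = np.diff(np.concatenate([np.zeros((1, 1)), cum], axis=1)).astype(int)
        session = make_manual_session(counts, onsets)
        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        deltas = trial_deltas(session, window)
        np.testing.assert_allclose(deltas, 10.0, atol=1.0)

    def test_poisson_null_mean_delta_near_zero(self):
        from somatodec.somatotopy import MovementWindow

        rng = np.random.default_rng(1)
        n_trials = 200
        onsets = [3.0 + 8.0 * i for i in range(n_trials)]
        counts = rng.poisson(0.4, (1, int((onsets[-1] + 5.5) * 50)))
        session = make_manual_session(counts, onsets)
        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        deltas = trial_deltas(session, window)
        se = np.sqrt(2 * 25 * 0.4 / n_trials)
        assert abs(deltas.mean()) < 4 * se

    def test_window_outside_recording_rejected(self):
        from somatodec.somatotopy import MovementWindow

        counts = np.zeros((1, 100), dtype=int)
        session = make_manual_session(counts, [0.3, 1.3], baseline_s=0.3,
                                      movement_s=0.5, rest_s=0.5)
        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        with pytest.raises(ValueError, match="extent"):
            trial_deltas(session, window)


class TestTuningTest:
    def test_default_threshold_is_bonferroni_for_four_movements(self):
        assert TuningTestConfig().alpha_per_test == pytest.approx(0.0125)

    def test_zero_deltas_not_significant(self):
        res = tuning_test(np.zeros(20))
        assert not res["significant"].iloc[0]
        assert res["p_value"].iloc[0] == 1.0
        assert res["degenerate"].iloc[0]

    def test_t_statistic_matches_hand_formula(self):
        deltas = np.array([3, 5, 4, 6, 2, 5, 4, 5, 3, 4, 5, 4, 6, 3, 4, 5, 4, 3, 5, 4],
                          dtype=float)
        res = tuning_test(deltas)
        n = len(deltas)
        t_oracle = deltas.mean() / (deltas.std(ddof=1) / np.sqrt(n))
        assert res["t_stat"].iloc[0] == pytest.approx(t_oracle, abs=1e-12)
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t_oracle), df=n - 1)
        assert res["p_value"].iloc[0] == pytest.approx(p_oracle, abs=1e-12)
        assert res["significant"].iloc[0]

    def test_vectorized_matches_rowwise(self):
        rng = np.random.default_rng(2)
        deltas = rng.normal(0.5, 2.0, (10, 15))
        batch = tuning_test(deltas)
        for i in range(10):
            row = tuning_test(deltas[i])
            assert batch["t_stat"].iloc[i] == pytest.approx(row["t_stat"].iloc[0])

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            tuning_test(np.array([1.0]))


class TestDepthOfModulation:
    def test_flat_rates_give_zero(self):
        from somatodec.somatotopy import MovementWindow

        counts = np.ones((2, 2000), dtype=int)
        session = make_manual_session(counts, [3.0, 11.0])
        sm = fabricate_smoothed(np.full((2, 2000), 20.0))
        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        np.testing.assert_allclose(depth_of_modulation(session, sm, window), 0.0)

    def test_full_window_bump_recovers_depth(self):
        from somatodec.somatotopy import MovementWindow

        rates = np.full((1, 2000), 10.0)
        onsets = [3.0, 11.0]
        for onset in onsets:
            b = int(onset * 50)
            rates[0, b : b + 25] = 22.0
        session = make_manual_session(np.zeros((1, 2000), dtype=int), onsets)
        sm = fabricate_smoothed(rates)
        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        np.testing.assert_allclose(
            depth_of_modulation(session, sm, window), 12.0, atol=1e-9
        )

    def test_largest_magnitude_excursion_kept_with_sign(self):
        from somatodec.somatotopy import MovementWindow

        rates = np.full((1, 2000), 10.0)
        for onset in (3.0, 11.0):
            b = int(onset * 50)
            rates[0, b : b + 10] = 13.0   # +3 excursion
            rates[0, b + 10 : b + 20] = 5.0  # -5 excursion
        session = make_manual_session(np.zeros((1, 2000), dtype=int), [3.0, 11.0])
        sm = fabricate_smoothed(rates)
        window = MovementWindow("grasp", 0.25, (0, 25), np.zeros(1), np.zeros(1))
        np.testing.assert_allclose(
            depth_of_modulation(session, sm, window), -5.0, atol=1e-9
        )


class TestProportionsAndMaps:
    @staticmethod
    def _results(flags: dict[tuple[int, str], bool], n_channels=4) -> pd.DataFrame:
        rows = []
        for ch in range(n_channels):
            for mv in MOVEMENTS:
                rows.append(
                    {
                        "channel_id": ch,
                        "array_id": "lateral",
                        "movement": mv,
                        "significant": flags.get((ch, mv), False),
                        "depth_of_modulation": 1.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_all_significant_gives_ones(self):
        flags = {(c, m): True for c in range(4) for m in MOVEMENTS}
        props = proportions_by_array(self._results(flags))
        assert (props["proportion"] == 1.0).all()

    def test_no_significant_gives_missing(self):
        props = proportions_by_array(self._results({}))
        assert props["proportion"].isna().all()

    def test_known_subsets_recovered(self):
        flags = {(0, "grasp"): True, (1, "grasp"): True, (1, "shoulder"): True,
                 (2, "wrist"): True}
        props = proportions_by_array(self._results(flags)).set_index("movement")
        assert props.loc["grasp", "proportion"] == pytest.approx(2 / 3)
        assert props.loc["shoulder", "proportion"] == pytest.approx(1 / 3)
        assert props.loc["elbow", "proportion"] == 0.0

    def test_heatmap_places_every_channel(self, somatotopy_session, somatotopy_smoothed):
        results, _ = map_session(somatotopy_session, somatotopy_smoothed)
        grid = depth_heatmap(results, somatotopy_session.array_map, "grasp", "lateral")
        n_lat = (somatotopy_session.array_map["array_id"] == "lateral").sum()
        assert np.isfinite(grid).sum() == n_lat


class TestRecovery:
    def test_strongly_tuned_channels_detected(self):
        """Depth >= 10 spikes/s on a 10 spikes/s baseline with 20 trials per
        movement is detected essentially always (analytic power at
        alpha=0.0125 far exceeds 0.99)."""
        cfg = GeneratorConfig(
            n_channels_per_array=12, n_blocks=20, seed=9, untuned_fraction=0.0,
            depth_base=10.0, depth_span=0.0, gradient_slope=0.0, depth_cv=0.0,
            baseline_rate_mean=10.0, baseline_rate_sd=0.0,
        )
        pop = make_population(cfg)
        session = simulate_somatotopy_session(pop, cfg)
        results, _ = map_session(session)
        assert results["significant"].mean() >= 0.95
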