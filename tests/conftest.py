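import numpy as np
import pandas as pd
import pytest

from somatodec import (
    GeneratorConfig,
    SessionBundle,
    make_population,
    preprocess_session,
    simulate_reach_grasp_session,
    simulate_somatotopy_session,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced-size generator settings for fast unit tests."""
    return GeneratorConfig(n_channels_per_array=32, n_blocks=6, n_reach_trials=8,
                           n_cursor_trials=12, n_click_epochs=4, seed=11)


@pytest.fixture(scope="session")
def population(small_config):
    return make_population(small_config)


@pytest.fixture(scope="session")
def somatotopy_session(population, small_config):
    return simulate_somatotopy_session(population, small_config)


@pytest.fixture(scope="session")
def somatotopy_smoothed(somatotopy_session):
    return preprocess_session(somatotopy_session.counts)


@pytest.fixture(scope="session")
def reach_session(population, small_config):
    return simulate_reach_grasp_session(population, small_config)


def make_manual_session(
    counts: np.ndarray,
    movement_onsets_s,
    movement: str = "grasp",
    baseline_s: float = 3.0,
    movement_s: float = 3.0,
    rest_s: float = 2.0,
) -> SessionBundle:
    """Hand-built session around a given count matrix (one movement type)."""
    onsets = np.asarray(movement_onsets_s, dtype=float)
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(len(onsets)),
            "movement_label": movement,
            "baseline_onset_s": onsets - baseline_s,
            "movement_onset_s": onsets,
            "rest_onset_s": onsets + movement_s,
            "end_s": onsets + movement_s + rest_s,
        }
    )
    n = counts.shape[0]
    array_map = pd.DataFrame(
        {
            "channel_id": np.arange(n),
            "array_id": np.where(np.arange(n) % 2 == 0, "lateral", "medial"),
            "grid_row": np.arange(n) // 10,
            "grid_col": np.arange(n) % 10,
            "mediolateral_pos": np.linspace(0, 1, n),
        }
    )
    return SessionBundle(counts=counts, trials=trials, array_map=array_map,
                         task="somatotopy")
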