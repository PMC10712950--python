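"""Shared fixtures: simulated datasets reused across test modules.

The heavier simulations are session-scoped so the generation cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from timedist.pipeline import PipelineConfig, load_dataset
from timedist.population import classify_dataset, shuffle_test


@pytest.fixture(scope="session")
def recovery_config() -> PipelineConfig:
    """Two sessions (one per type) x 40 runs x 60 cells: 20 time cells in the
    fixed-time session, 20 distance cells in the fixed-distance session, 10
    untuned cells in each; peak 20 Hz, baseline 0.5 Hz, onset jitter 0.2 s."""
    return PipelineConfig(
        n_sessions_fixed_time=1,
        n_sessions_fixed_distance=1,
        n_runs=40,
        n_time_cells=20,
        n_distance_cells=20,
        n_untuned_cells=10,
        peak_rate=20.0,
        baseline_rate=0.5,
        onset_jitter_sd=0.2,
        seed=1,
    )


@pytest.fixture(scope="session")
def recovery_dataset(recovery_config):
    return load_dataset(recovery_config)


@pytest.fixture(scope="session")
def recovery_results(recovery_dataset):
    """(onset tables, encoding results) for the recovery dataset, defaults."""
    return classify_dataset(recovery_dataset)


@pytest.fixture(scope="session")
def multi_session_dataset():
    """Ten sessions (5 per type), tuned cells aligned with their session type;
    used where the session-label permutation group must be nondegenerate."""
    cfg = PipelineConfig(
        n_sessions_fixed_time=5,
        n_sessions_fixed_distance=5,
        n_runs=40,
        n_time_cells=6,
        n_distance_cells=6,
        n_untuned_cells=2,
        seed=7,
    )
    return load_dataset(cfg)


@pytest.fixture(scope="session")
def multi_session_shuffle(multi_session_dataset):
    return shuffle_test(multi_session_dataset, n_shuffles=200, seed=11)


@pytest.fixture(scope="session")
def untuned_dataset():
    """Six sessions (3 per type) of untuned cells only: exchangeable across
    session types, so every population statistic is under its null."""
    cfg = PipelineConfig(
        n_sessions_fixed_time=3,
        n_sessions_fixed_distance=3,
        n_runs=40,
        n_time_cells=0,
        n_distance_cells=0,
        n_untuned_cells=20,
        seed=5,
    )
    return load_dataset(cfg)
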