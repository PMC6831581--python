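"""Shared fixtures: a small synthetic study and the palpation-table fixture."""

import numpy as np
import pytest

from synreach import pipeline, synthgen, tpstats


@pytest.fixture(scope="session")
def small_config() -> synthgen.GenerativeConfig:
    """Reduced study (3 subjects, 1024 Hz EMG) for fast end-to-end tests."""
    return synthgen.GenerativeConfig(
        n_subjects=3, sampling_rate_emg=1024.0, snr_db=20.0, seed=42
    )


@pytest.fixture(scope="session")
def small_ground_truth(small_config):
    return synthgen.make_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_ground_truth):
    """Preprocessed small study shared across tests (read-only)."""
    return pipeline.preprocess_study(small_config, small_ground_truth)


@pytest.fixture(scope="session")
def palpation_table() -> tpstats.TPTable:
    return tpstats.load_tp_table(tpstats.bundled_palpation_path())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
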