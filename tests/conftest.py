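import numpy as np
import pytest

from rnastab.synthetic import (SimConfig, simulate_compartment,
                               simulate_decay_profiles, simulate_transcriptome)


@pytest.fixture(scope="session")
def small_sim():
    """Small but realistic synthetic experiment shared across tests."""
    cfg = SimConfig(n_transcripts=40, seed=11)
    records, truth = simulate_transcriptome(cfg)
    profiles = simulate_decay_profiles(truth, cfg)
    return cfg, records, truth, profiles


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = SimConfig(n_transcripts=15, seed=3, noise_sigma=0.0,
                    detection_floor=0.0)
    records, truth = simulate_transcriptome(cfg)
    profiles = simulate_decay_profiles(truth, cfg)
    return cfg, records, truth, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
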