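"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from affectpipe import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.SimConfig:
    cfg = syn.SimConfig(n_participants=12, seed=42)
    cfg.timeline_sizes = (24, 8, 6)
    return cfg


@pytest.fixture(scope="session")
def cohort(small_config):
    return syn.generate_cohort(small_config)


@pytest.fixture(scope="session")
def cognitive_logs(cohort, small_config):
    return syn.simulate_cognitive_logs(cohort, small_config)


@pytest.fixture(scope="session")
def timeline(small_config):
    return syn.build_timeline(small_config)


@pytest.fixture(scope="session")
def eeg_sim(timeline, small_config):
    """One simulated EEG recording with blinks and injected artifacts."""
    cfg = syn.SimConfig(n_participants=12, seed=7)
    cfg.timeline_sizes = (24, 8, 6)
    cfg.eeg.artifact_rate_hz = 0.03
    return syn.simulate_eeg("P000", timeline, cfg)


@pytest.fixture(scope="session")
def wristband_sim(timeline, small_config):
    return syn.simulate_wristband("P000", timeline, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
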