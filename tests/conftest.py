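import dataclasses

import pytest
from hypothesis import settings

from equispine import MarkerConfig, analyze_trial, simulate_trot_markers
from equispine.synthetic_data import TrotSimConfig

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def id_config() -> MarkerConfig:
    return MarkerConfig.identity()


@pytest.fixture(scope="session")
def clean_cfg() -> TrotSimConfig:
    """Noise-free straight-line trot with default amplitudes."""
    return TrotSimConfig(noise_sd_mm=0.0)


@pytest.fixture(scope="session")
def clean_series(clean_cfg):
    return simulate_trot_markers(clean_cfg)


@pytest.fixture(scope="session")
def clean_result(clean_series, id_config):
    return analyze_trial(clean_series, id_config)


@pytest.fixture(scope="session")
def noisy_series():
    return simulate_trot_markers(TrotSimConfig(seed=5))


def make_cfg(**kw) -> TrotSimConfig:
    return dataclasses.replace(TrotSimConfig(), **kw)
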