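import numpy as np
import pytest

from meditfc import SynthConfig, extract_cohort_features, generate_cohort
from meditfc.synthetic import uniform_band_coupling


@pytest.fixture(scope="session")
def small_config():
    """Two subjects per group, two short states: cheap but full-structure."""
    return SynthConfig(
        n_per_group={"LTM": 2, "STM": 2, "NM": 2},
        state_durations={"baseline": 20.0, "meditation": 20.0},
        noise_sd=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def full_state_features():
    """A tiny cohort covering all four states (for grid-shaped outputs)."""
    config = SynthConfig(
        n_per_group={"LTM": 2, "STM": 2, "NM": 2},
        state_durations={
            "baseline": 40.0,
            "meditation": 40.0,
            "transmission": 40.0,
            "post": 40.0,
        },
        noise_sd=0.2,
        seed=11,
    )
    return extract_cohort_features(generate_cohort(config))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_coupling():
    return uniform_band_coupling
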