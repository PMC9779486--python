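import numpy as np
import pytest

from petreach.synth import SynthConfig, default_regions, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def noise_free_config() -> SynthConfig:
    """Every stochastic knob off: closed-form checks become exact."""
    return SynthConfig(
        regions=default_regions(sigma=0.0, reference_sigma=0.0),
        scan_scale_sd=0.0,
        lesion_area_sd=0.0,
        lesion_scale_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(default_config):
    return generate_cohort(default_config, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
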