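import numpy as np
import pytest

from fieldcycle import (GeneratorConfig, gen_coil_responses,
                        gen_shield_background)
from fieldcycle.fieldmap import (MM_PER_USTEP, USTEPS_FULL_TRAVEL,
                                 Z_SAMPLE_PERCENT)


@pytest.fixture(scope="session")
def cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def background(cfg):
    return gen_shield_background(cfg)


@pytest.fixture(scope="session")
def coils(cfg):
    return gen_coil_responses(cfg)


@pytest.fixture(scope="session")
def sample_positions(background):
    """Grid points inside the 5 cm sample region around z_sample."""
    center = Z_SAMPLE_PERCENT / 100 * USTEPS_FULL_TRAVEL
    half = 25.0 / MM_PER_USTEP  # 2.5 cm in microsteps
    pos = background.position_usteps
    return pos[(pos >= center - half) & (pos <= center + half)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
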