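import numpy as np
import pytest

from palmage.mosaic import build_annual_mosaic
from palmage.synthetic import (ScenarioConfig, generate_landscape,
                               simulate_sar_stack)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A 96x96 scene: small enough for fast tests, large enough for the
    patch structure and grid tiling to be meaningful."""
    return ScenarioConfig(rows=96, cols=96, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_scenes(small_config, small_truth):
    return simulate_sar_stack(small_truth, small_config)


@pytest.fixture(scope="session")
def small_mosaic(small_scenes):
    return build_annual_mosaic(small_scenes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
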