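import numpy as np
import pytest

from dielact.solar_time import SolarAnchors, hours_to_radians
from dielact.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture
def anchors_6_18():
    return SolarAnchors(float(hours_to_radians(6)), float(hours_to_radians(18)))


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study: 3 regions x 2 landscapes, ~250 detections each."""
    cfg = GeneratorConfig(seed=42, landscapes_per_region=2,
                          cameras_per_landscape=8, detections_mean=32.0)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
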