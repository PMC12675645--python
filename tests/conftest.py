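import numpy as np
import pytest

from fluorosynth.phantom import PhantomConfig
from fluorosynth.projection import DetectorConfig


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Coarse 48^3 phantom (4 mm voxels) for fast unit tests."""
    return PhantomConfig(shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0), tumor_diameter_mm=14.0)


@pytest.fixture(scope="session")
def tiny_detector() -> DetectorConfig:
    return DetectorConfig(output_shape=(32, 32))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
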