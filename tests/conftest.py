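import numpy as np
import pytest

from cardiomotion import SyntheticScene, VideoStack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """The default 128x128 synthetic scene (geometry cached across tests)."""
    return SyntheticScene()


@pytest.fixture(scope="session")
def texture128(default_scene):
    return default_scene.texture


@pytest.fixture()
def small_stack(rng):
    """A small random unit-range video for oracle comparisons."""
    return VideoStack(rng.random((8, 8, 8)), bit_depth="unit", frame_interval_ms=2.0)
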