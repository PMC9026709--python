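import numpy as np
import pytest

from sepatrack import SimScene, simulate_sequence
from sepatrack.core_io import PipelineConfig


@pytest.fixture(scope="session")
def short_sequence():
    """An 80-frame arena sequence with a moderate occlusion schedule."""
    scene = SimScene(occlusion_fraction=0.2, seed=11)
    return simulate_sequence(scene, 80)


@pytest.fixture(scope="session")
def occluding_sequence():
    """A sequence rich in occluding frames (for segmentation tests)."""
    scene = SimScene(occlusion_fraction=0.5, seed=3)
    return simulate_sequence(scene, 60)


@pytest.fixture()
def cfg():
    return PipelineConfig(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, shape=(16, 16), p=0.4):
    """Random boolean mask; used by brute-force metric oracles."""
    return rng.random(shape) < p
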