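import numpy as np
import pytest

from orthotrack import AnatomicalFrame, CupOrientation, ScenarioConfig, StemOrientation
from orthotrack.simulator import generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20221214)


@pytest.fixture
def canonical_frame():
    """Axis-aligned anatomical frame: longitudinal +x, anterior +y, lateral +z."""
    return AnatomicalFrame(
        lateral=np.array([0.0, 0.0, 1.0]),
        anterior=np.array([0.0, 1.0, 0.0]),
        longitudinal=np.array([1.0, 0.0, 0.0]),
    )


@pytest.fixture
def noiseless_config():
    return ScenarioConfig(seed=11, marker_sigma_m=0.0, tracker_rot_sigma_deg=0.0)


@pytest.fixture
def cup_scene(noiseless_config, rng):
    return generate_scene(CupOrientation(20.0, 45.0), noiseless_config, rng)


@pytest.fixture
def stem_scene(noiseless_config, rng):
    return generate_scene(StemOrientation(15.0, 3.0), noiseless_config, rng)
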