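import numpy as np
import pytest

from vwisim.params import TissueParams, default_protocols
from vwisim.phantom import compact_scene, build_phantom, calibrate_noise


@pytest.fixture(scope="session")
def wall():
    return TissueParams(1114.0, 55.0, 1.0, "wall")


@pytest.fixture(scope="session")
def lossless():
    return TissueParams(np.inf, np.inf, 1.0, "lossless")


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def built_default(protocols):
    """One built + noise-calibrated default scene, shared across tests."""
    scene = compact_scene(seed=11)
    built = build_phantom(scene)
    scene.noise_sigma = calibrate_noise(scene, protocols, built=built)
    return built


@pytest.fixture(scope="session")
def straight_built():
    """Axis-aligned straight-tube scene for analytic geometry checks."""
    scene = compact_scene(seed=3, straight=True)
    return build_phantom(scene)
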