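import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lgquant import (NOISELESS, MultiChannelVolume, NoiseModel, SceneParams,
                     render_scene, sample_scene)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """20 well-separated nuclei with a 30% plasmatocyte fraction."""
    params = SceneParams(shape=(24, 96, 96), spacing=(1.0, 0.3, 0.3),
                         n_nuclei=20, psc_count=0,
                         marker_fractions={"plasmatocyte": 0.3})
    return sample_scene(params, seed=11)


@pytest.fixture(scope="session")
def small_volume_clean(small_scene):
    return render_scene(small_scene, NOISELESS)


@pytest.fixture(scope="session")
def small_volume_noisy(small_scene):
    return render_scene(small_scene, NoiseModel())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def tiny_volume():
    """Deterministic 2-channel volume for I/O and ROI tests."""
    gen = np.random.default_rng(7)
    return MultiChannelVolume(
        channels={"dapi": gen.integers(0, 4096, size=(8, 16, 16)).astype(np.uint16),
                  "red": gen.integers(0, 4096, size=(8, 16, 16)).astype(np.uint16)},
        spacing=(1.0, 0.3, 0.3))
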