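import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """One 64x64 synthetic scene, unit-normalized."""
    import partialscan as ps

    p = ps.SceneParams(image_size=(64, 64), seed=11)
    return ps.normalize(ps.generate_scene(p))


@pytest.fixture
def quiet_scene():
    """Noise-free 64x64 scene (for exact-recovery style checks)."""
    import partialscan as ps

    p = ps.SceneParams(image_size=(64, 64), seed=5,
                       line_noise_sd=0.0, pixel_noise_sd=0.0)
    return ps.normalize(ps.generate_scene(p))
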