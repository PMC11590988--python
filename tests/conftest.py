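import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def pen_scene():
    """A mid-sized deterministic day scene with a handful of goats."""
    from goatvision.synthetic import PenSceneConfig, generate_pen_image
    return generate_pen_image(
        PenSceneConfig(image_size=(640, 360), n_goats=6, seed=42))


@pytest.fixture
def small_scenes():
    """Ten small day scenes used by training/eval tests."""
    from goatvision.synthetic import PenSceneConfig, generate_pen_image
    return [
        generate_pen_image(PenSceneConfig(image_size=(320, 320), n_goats=3,
                                          occlusion_level=0.4, seed=100 + i))
        for i in range(10)
    ]
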