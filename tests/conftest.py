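import numpy as np
import pytest

from pointcount import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_scene():
    """A well-separated, occlusion-free scene with exact ground truth."""
    cfg = SceneConfig(image_size=(128, 128), count_range=(8, 12),
                      seed_radius_range=(5.0, 6.0), min_separation=20.0,
                      occluder_fraction=0.0, rng_seed=7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def tiny_feature_map():
    r = np.random.default_rng(0)
    return r.normal(size=(2, 8, 16, 16)).astype(np.float32)
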