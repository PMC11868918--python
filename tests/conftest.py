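import numpy as np
import pytest

from mechscope import (
    CantileverSpec,
    RampConfig,
    SceneConfig,
    render_images,
    sample_scene,
)


@pytest.fixture(scope="session")
def cantilever():
    return CantileverSpec(k_n_per_m=0.05, tip_radius_um=5.0)


@pytest.fixture(scope="session")
def ramp():
    return RampConfig(z_start_um=0.0, z_end_um=5.0, samples_per_segment=400, setpoint_nN=5.0)


@pytest.fixture(scope="session")
def high_scene():
    """One default high-density scene + rendered images (session-cached)."""
    cfg = SceneConfig.high_density()
    gt = sample_scene(cfg, seed=1)
    images = render_images(gt, cfg)
    return cfg, gt, images


@pytest.fixture(scope="session")
def low_scene():
    cfg = SceneConfig.low_density()
    gt = sample_scene(cfg, seed=1)
    images = render_images(gt, cfg)
    return cfg, gt, images


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
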