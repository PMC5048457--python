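import numpy as np
import pytest

from pulsecam.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 10-second 120×160 scene with ≈8,500 skin pixels at 72 beats/min."""
    config = SceneConfig(
        shape=(120, 160),
        skin_ellipse=(60, 80, 45, 60),
        duration_s=10.0,
        seed=11,
    )
    seq, truth = generate_scene(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def textured_frame():
    """A static 120×160 frame with an elliptical textured patch."""
    config = SceneConfig(
        shape=(120, 160),
        skin_ellipse=(60, 80, 45, 60),
        duration_s=1.0 / 30.0,
        seed=4,
        jitter_max_step=0,
        cluster_noise_per_frame=0,
        noise_sigma=0.0,
    )
    seq, _ = generate_scene(config)
    return seq.frame(0)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
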