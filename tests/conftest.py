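import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rcpscope.synthscope import SceneConfig, render_scene

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sparse_scene():
    """Two-channel 512^2 scene: 60 RCPs (50:50 bases), 12 artifacts."""
    cfg = SceneConfig(image_height_px=512, image_width_px=512,
                      spot_density=60, artifact_density=12,
                      mutant_fraction=0.5, seed=41)
    stacks, truth = render_scene(cfg)
    return cfg, stacks, truth


@pytest.fixture(scope="session")
def anchor_scene():
    """Scene with the anchor channel stained on RCPs but not artifacts."""
    cfg = SceneConfig(image_height_px=512, image_width_px=512,
                      spot_density=40, artifact_density=15,
                      mutant_fraction=0.5, include_anchor=True, seed=42)
    stacks, truth = render_scene(cfg)
    return cfg, stacks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
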