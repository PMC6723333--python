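import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phototherm as pt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return pt.default_config()


@pytest.fixture(scope="session")
def small_setup():
    """Default scenario compiled on a coarse grid for fast transport runs."""
    cfg = pt.default_config()
    cfg.grid.n_cells = 61
    scene = pt.build_scene(cfg)
    source = pt.build_source(cfg)
    material_index = scene.voxelize()
    return cfg, scene, source, material_index


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
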