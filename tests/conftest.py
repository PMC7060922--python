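import numpy as np
import pytest

from glut4tirf import AcquisitionGeometry, SimulationConfig, simulate_tirf_movie


@pytest.fixture
def geometry():
    return AcquisitionGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noisy_movie():
    """A small seeded movie with both vesicle classes and realistic noise."""
    geom = AcquisitionGeometry(frame_interval=2.0, exposure=0.5)
    cfg = SimulationConfig(field_size=(128, 128), duration_pre=60,
                           duration_post=120, seed=7)
    movie, truth = simulate_tirf_movie(cfg, geom)
    return movie, truth, cfg
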