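import numpy as np
import pytest

from henorm import synthetic


@pytest.fixture(scope="session")
def small_params():
    """Small scene for fast tests."""
    return synthetic.SceneParams(height=128, width=128, n_nuclei=8)


@pytest.fixture(scope="session")
def scene(small_params):
    return synthetic.generate_scene(small_params, seed=7)


@pytest.fixture(scope="session")
def rendered(scene):
    return synthetic.render(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rgb(rng, h=32, w=32):
    return rng.integers(0, 256, (h, w, 3)).astype(np.uint8)
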