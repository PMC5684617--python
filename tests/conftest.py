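import numpy as np
import pytest

from capsenhance import EnhanceParams, SceneParams, generate_scene


@pytest.fixture(scope="session")
def default_params():
    return EnhanceParams()


@pytest.fixture(scope="session")
def scene():
    """One default synthetic frame with truth masks."""
    return generate_scene(SceneParams(seed=0))


@pytest.fixture(scope="session")
def scenes10():
    """Ten seeded synthetic frames, the standard evaluation batch."""
    return [generate_scene(SceneParams(seed=s)) for s in range(10)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rgb(rng, h, w):
    """Uniform random RGB image in [0, 1]."""
    return rng.uniform(0.0, 1.0, size=(h, w, 3))
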