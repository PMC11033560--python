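import numpy as np
import pytest

from pcmfiber import easy_scene_spec, generate_scene


@pytest.fixture(scope="session")
def easy_scene():
    """One high-contrast synthetic field (image, truth fibers, annotations)."""
    spec = easy_scene_spec(seed=1)
    return spec, generate_scene(spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, n_points=40, spread=20):
    """A random connected-ish pixel cloud for rectangle/matching tests."""
    center = rng.uniform(10, 50, size=2)
    pts = center + rng.normal(0, spread / 4, size=(n_points, 2))
    coords = np.unique(np.round(pts).astype(int), axis=0)
    return coords
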