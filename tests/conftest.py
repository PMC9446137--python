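import numpy as np
import pytest

import woundlabel as wl


def random_raster(rng: np.random.Generator, h: int, w: int) -> wl.RasterImage:
    """Random 8-bit-grid image, the worst case for tie handling."""
    return wl.RasterImage(rng.integers(0, 256, size=(h, w, 3)) / 255.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fixture_scenes():
    """The six pinned-seed study scenes (generated once per session)."""
    return [wl.generate_scene(p) for p in wl.fixture_scene_params()]
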