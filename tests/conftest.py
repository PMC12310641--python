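import numpy as np
import pytest

from lidcurve.synth import rasterize_masks, sample_eye_geometry


@pytest.fixture(scope="session")
def eye_geometry():
    """One deterministic synthetic eye at the default canvas."""
    return sample_eye_geometry(0)


@pytest.fixture(scope="session")
def eye_masks(eye_geometry):
    return rasterize_masks(eye_geometry)


@pytest.fixture(scope="session")
def big_eye():
    """High-resolution eye (corneal diameter > 400 px) with its masks."""
    g = sample_eye_geometry(7, height=992, width=1488)
    return g, rasterize_masks(g)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
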