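import numpy as np
import pytest

from greenview import RGBImage, NIRImage, make_worked_example


@pytest.fixture(scope="session")
def location1():
    return make_worked_example(1)


@pytest.fixture(scope="session")
def location2():
    return make_worked_example(2)


def random_scene(rng, h=10, w=10):
    """A random RGB+NIR pair for oracle-equivalence checks."""
    rgb = RGBImage(rng.random((h, w)), rng.random((h, w)), rng.random((h, w)))
    nir = NIRImage(rng.random((h, w)))
    return rgb, nir


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
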