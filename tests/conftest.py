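import numpy as np
import pytest

from msheadem.core import LabelVolume
from msheadem.phantoms import default_head_spec, make_head_phantom


@pytest.fixture(scope="session")
def head_spec():
    return default_head_spec(seed=0)


@pytest.fixture(scope="session")
def head_coarse(head_spec):
    vol, lms = make_head_phantom(head_spec, 1.0)
    return vol, lms


@pytest.fixture(scope="session")
def head_fine(head_spec):
    vol, lms = make_head_phantom(head_spec, 0.2)
    return vol, lms


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sphere_volume():
    """Analytic sphere of radius 10 mm rasterised at 0.5 mm."""
    sp = 0.5
    n = 48
    ax = -12.0 + (np.arange(n) + 0.5) * sp
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
    mask = (pts**2).sum(-1) <= 100.0
    return LabelVolume(mask.astype(np.int16), sp, np.full(3, -12.0))
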