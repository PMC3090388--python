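import numpy as np
import pytest
from scipy import ndimage

from lipovol.core import VolumeMap
from lipovol.phantom import default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def blob_volume() -> VolumeMap:
    """Smooth, asymmetric, compactly supported test volume (48^3).

    Unlike the quasi-spherical lipoprotein phantom, this object has no
    approximate rotational symmetry, so orientation-recovery tests are well
    conditioned on it.
    """
    rng = np.random.default_rng(5)
    data = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 2.5)
    zz, yy, xx = np.mgrid[:48, :48, :48]
    c = (48 - 1) / 2
    data *= ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) < 18**2
    return VolumeMap(data.astype(np.float32), 1.0)


@pytest.fixture(scope="session")
def ordered_phantom() -> VolumeMap:
    return make_phantom(default_phantom_spec("ordered"))


@pytest.fixture(scope="session")
def disordered_phantom() -> VolumeMap:
    return make_phantom(default_phantom_spec("disordered"))
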