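import warnings

import numpy as np
import pytest

from acspect.phantom import build_phantom, default_phantom_spec
from acspect.volume import VolumeImage

# the shallowest tabulated kernel depth is queried by every near-surface
# slice; the clamp warning is expected and assessed explicitly in the
# scatter tests
warnings.filterwarnings(
    "ignore", message="depth below tabulated kernel range.*"
)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Three-sphere phantom at desk scale (64^3, 7.2 mm voxels)."""
    spec = default_phantom_spec(voxel_size_mm=7.2, grid=64)
    act, mu, labels = build_phantom(spec)
    return spec, act, mu, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_volume():
    """A 32^3 random non-negative volume, 7.2 mm voxels."""
    data = np.random.default_rng(7).random((32, 32, 32))
    return VolumeImage(data, 7.2)
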