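import numpy as np
import pytest

from brainmech import PhantomSpec, make_phantom, trim_to_mask


@pytest.fixture(scope="session")
def stretch_phantom():
    """Static uniaxial-stretch phantom (exact affine displacement)."""
    spec = PhantomSpec(kind="uniaxial_stretch", amplitude=0.05, n_t=1, shape=(12, 12, 12))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def pulsatile_phantom():
    """Smooth pulsatile phantom over 8 cardiac phases."""
    spec = PhantomSpec(kind="pulsatile_composite", amplitude=0.15, n_t=8,
                       shape=(14, 14, 14))
    return make_phantom(spec)


@pytest.fixture
def trimmed_stretch(stretch_phantom):
    field, labels, truth = stretch_phantom
    return trim_to_mask(field, labels), labels, truth


def interior_mask(labels):
    """In-brain voxels whose six face neighbours are also in-brain."""
    from scipy import ndimage

    return ndimage.binary_erosion(labels.brain_mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240801)
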