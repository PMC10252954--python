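import numpy as np
import pytest

from perfectsyn.core import BinaryMask, ImageVolume, VectorField
from perfectsyn.phantom import PhantomSpec, generate_phantom_pair, sample_population


@pytest.fixture(scope="session")
def default_pair():
    """One phantom pair at the package's standard study conditions."""
    return generate_phantom_pair(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def fine_pairs():
    """Phantom pairs at treatment-planning in-plane resolution (~2.7 mm),
    used where sub-voxel geometric consistency is asserted."""
    spec = PhantomSpec(shape=(48, 96, 96), spacing=(4.0, 8.0 / 3.0, 8.0 / 3.0))
    return sample_population(6, base_spec=spec, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_volume(rng, shape=(8, 9, 10), spacing=(2.0, 1.5, 1.0)):
    return ImageVolume(rng.uniform(-800, 800, shape).astype(np.float32), spacing)


def random_field(rng, shape=(8, 9, 10), spacing=(2.0, 1.5, 1.0), amp=3.0):
    return VectorField(
        rng.uniform(-amp, amp, (3, *shape)).astype(np.float32), spacing
    )


def random_mask(rng, shape=(8, 9, 10), spacing=(2.0, 1.5, 1.0), p=0.3):
    return BinaryMask((rng.random(shape) < p).astype(np.uint8), spacing)
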