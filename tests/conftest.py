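import numpy as np
import pytest

from invertseg import PhantomSpec, Volume, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_volume(data, spacing=(1.0, 1.0, 1.0), tag="other"):
    data = np.asarray(data)
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return Volume(data=data, spacing=np.asarray(spacing, float), affine=affine,
                  modality_tag=tag)


@pytest.fixture
def volume_factory():
    return make_volume


@pytest.fixture(scope="session")
def default_case():
    """One spec-default phantom subject (96 cube at 2 mm), shared read-only."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom spec for structural tests."""
    return PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(3.0, 3.0, 3.0),
                       tumor_volume_cm3=12.0, seed=9)
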