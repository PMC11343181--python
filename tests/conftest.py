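import numpy as np
import pytest

from q3d import (
    AffineTransform,
    PhantomSpec,
    Volume3D,
    fit_native_to_atlas,
    generate_toy_atlas,
)


@pytest.fixture(scope="session")
def toy_atlas():
    return generate_toy_atlas((16, 16, 16), 4, seed=7)


@pytest.fixture(scope="session")
def identity_transform():
    return AffineTransform.identity()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_spec(toy_atlas):
    # native physical extent matched to the toy atlas (16 * 25 µm = 400 µm)
    return PhantomSpec(
        shape=(32, 32, 32),
        spacing_um=(12.5, 12.5, 12.5),
        noise_sd=1.0,
        object_rate=2000.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_transform(small_phantom_spec, toy_atlas):
    return fit_native_to_atlas(
        small_phantom_spec.shape, small_phantom_spec.spacing_um, toy_atlas
    )


def flat_volume(value=100.0, shape=(24, 24, 24), spacing=(3.26, 3.26, 3.0)):
    return Volume3D(np.full(shape, float(value)), spacing)
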