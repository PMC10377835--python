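import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disk(radius: int, pad: int = 10) -> np.ndarray:
    side = 2 * radius + 2 * pad + 1
    yy, xx = np.indices((side, side))
    c = side // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


@pytest.fixture
def disk20():
    return make_disk(20)


@pytest.fixture
def textured_ellipse():
    """Flat background with a clearly textured elliptical lesion."""
    from oraldx.synthetic import SyntheticImageSpec, generate_image

    spec = SyntheticImageSpec(
        kind="cancer",
        seed=7,
        background_amplitude=0.0,
        impulse_fraction=0.0,
        gaussian_sigma=0.0,
    )
    return generate_image(spec)
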