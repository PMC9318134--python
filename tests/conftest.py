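import numpy as np
import pytest

from ihcquant import FieldGenParams, add_background_noise, generate_field


@pytest.fixture(scope="session")
def good_field():
    """A small clean field: 96x96 px, ~15% stained, fixed seed."""
    return generate_field(FieldGenParams(target_fraction=15.0, seed=11, extent=(96, 96)))


@pytest.fixture(scope="session")
def noise_field(good_field):
    """The paired noise-regime version of ``good_field``."""
    return add_background_noise(good_field, noise_intensity=0.5, seed=23)


@pytest.fixture(scope="session")
def paired_fields():
    """Several (GOOD, NOISE) field pairs at varied fractions, 128x128 px."""
    pairs = []
    for i, frac in enumerate((4.0, 9.0, 15.0, 22.0, 28.0)):
        g = generate_field(
            FieldGenParams(target_fraction=frac, seed=100 + i, extent=(128, 128))
        )
        n = add_background_noise(g, noise_intensity=0.5, seed=200 + i)
        pairs.append((g, n))
    return pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
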