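import numpy as np
import pytest

from dnamoire import fft_recovery as fr
from dnamoire import synthetic_imaging as si


@pytest.fixture(scope="session")
def bilayer_fixture():
    """Square bilayer at the seed-S-like twist, modest image for speed."""
    image, truth, params = si.make_fixture(
        "bilayer", rng_seed=7, twist_deg=5.0, image_size=512
    )
    return image, truth, params


@pytest.fixture(scope="session")
def bilayer_spectrum(bilayer_fixture):
    image, truth, params = bilayer_fixture
    return fr.power_spectrum(image, params.pixel_size_nm), truth


@pytest.fixture(scope="session")
def monolayer_fixture():
    image, truth, params = si.make_fixture("monolayer", rng_seed=3, image_size=512)
    return image, truth, params
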