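import numpy as np
import pytest

from histodti.images import Micrograph
from histodti.phantoms import AstroPhantomSpec, NisslPhantomSpec, generate_astrocytes, generate_nissl


@pytest.fixture(scope="session")
def astro_phantom():
    """One noiseless astrocyte phantom with planted sub-cut-off fragments."""
    spec = AstroPhantomSpec(seed=7, n_fragments=2)
    img, truth = generate_astrocytes(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def nissl_phantom():
    spec = NisslPhantomSpec(seed=7, image_size=(512, 512), pixel_size=0.228, n_cells=25)
    img, truth = generate_nissl(spec)
    return spec, img, truth


@pytest.fixture()
def grating():
    """Vertical grating (intensity varies along columns), period 8 px."""
    _, x = np.mgrid[0:192, 0:192]
    pixels = (128 + 100 * np.sin(2 * np.pi * x / 8)).astype(np.uint8)
    return Micrograph(pixels, 0.114)
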