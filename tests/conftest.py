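import numpy as np
import pytest

from asphere.synthetic import PhantomSpec, ShapeSpec, make_phantom


@pytest.fixture(scope="session")
def sphere_phantom_2mm():
    """Noiseless sphere r=15 mm, 10:1 contrast, PSF 8 mm, SPECT-like 2 mm grid."""
    spec = PhantomSpec(
        shape=ShapeSpec("sphere", (15.0, 15.0, 15.0)),
        grid_shape=(72, 72, 72),
        spacing_mm=(2.0, 2.0, 2.0),
        psf_fwhm_mm=8.0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_phantom_sharp():
    """Noiseless unblurred sphere r=15 mm: segmentation should be near-exact."""
    spec = PhantomSpec(
        shape=ShapeSpec("sphere", (15.0, 15.0, 15.0)),
        grid_shape=(72, 72, 72),
        spacing_mm=(2.0, 2.0, 2.0),
        psf_fwhm_mm=0.0,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
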