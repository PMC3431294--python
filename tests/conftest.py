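import numpy as np
import pytest

from atd import OpticalConfig, synthetic_psf


@pytest.fixture(scope="session")
def cfg_488():
    """488 nm emission, 1.4 NA oil objective, 100 nm pixels."""
    return OpticalConfig(wavelength_nm=488.0, numerical_aperture=1.4, pixel_nm=100.0)


@pytest.fixture(scope="session")
def gauss_psf(cfg_488):
    """Reference wide-field-like Gaussian PSF: FWHM 3.2 px at 100 nm pixels."""
    return synthetic_psf(cfg_488, "gaussian", fwhm_nm=320.0, window_px=21)


@pytest.fixture(scope="session")
def bead_airy_psf(cfg_488):
    """Airy PSF convolved with a 110 nm bead disc (what a bead images as)."""
    return synthetic_psf(cfg_488, "bead_convolved_airy", bead_diameter_nm=110.0, window_px=15)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
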