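import numpy as np
import pytest

from sheetquant.core_io import AnalysisConfig, Micrograph


def gaussian_spot_image(
    shape=(64, 64),
    center=(32.0, 32.0),
    amplitude=100.0,
    sigma_px=1.5,
    background=0.0,
    pixel_size_nm=25.0,
):
    """Noiseless isotropic Gaussian spot on a constant background."""
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    field = background + amplitude * np.exp(
        -(((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2.0 * sigma_px**2))
    )
    return Micrograph(field, pixel_size_nm=pixel_size_nm)


@pytest.fixture
def spot_image():
    return gaussian_spot_image


@pytest.fixture
def default_cfg():
    return AnalysisConfig()
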