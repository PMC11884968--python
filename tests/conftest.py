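import numpy as np
import pytest

from mmspec import AcquisitionMeta, SpectralAxis, Spectrum


@pytest.fixture
def raman_axis():
    return SpectralAxis(np.arange(350.0, 1901.0, 1.0), "raman_shift_cm-1")


@pytest.fixture
def drs_axis():
    return SpectralAxis(np.arange(450.0, 801.0, 1.0), "wavelength_nm")


@pytest.fixture
def flat_raman(raman_axis):
    return Spectrum(raman_axis, np.full(len(raman_axis), 10.0), AcquisitionMeta())


def gaussian(x, center, amplitude, fwhm):
    return amplitude * np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)
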