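import numpy as np
import pytest

from fluorospec.spectra_io import Spectrum, SpectrumGroup, load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture
def toy_spectrum():
    """A smooth single-peaked spectrum on a 2 nm grid, peak at 430 nm."""
    wl = np.arange(300.0, 651.0, 2.0)
    inten = np.exp(-0.5 * ((wl - 430.0) / 40.0) ** 2)
    return Spectrum(266.0, wl, inten, condition="AD", replicate_id="1")


def make_spectrum(intensities, *, start=300.0, step=2.0, excitation=266.0, **kwargs):
    intensities = np.asarray(intensities, dtype=float)
    wl = start + step * np.arange(len(intensities))
    return Spectrum(excitation, wl, intensities, **kwargs)


def make_group(rows, *, condition="AD", excitation=266.0, **kwargs):
    spectra = [
        make_spectrum(row, excitation=excitation, condition=condition,
                      replicate_id=str(i + 1), **kwargs)
        for i, row in enumerate(rows)
    ]
    return SpectrumGroup(excitation, condition, spectra)
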