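import numpy as np
import pytest

from faruvc import synthetic
from faruvc.spectra import SpectralDistribution


@pytest.fixture(scope="session")
def skin_preset():
    return synthetic.make_skin_preset()


@pytest.fixture(scope="session")
def lamp_unfiltered():
    return synthetic.make_lamp_spectrum(filtered="unfiltered")


@pytest.fixture(scope="session")
def lamp_filtered():
    return synthetic.make_lamp_spectrum(filtered="filtered")


@pytest.fixture
def flat_absolute_spectrum():
    """1 mW cm^-2 nm^-1 flat over 200-400 nm."""
    w = np.arange(200.0, 401.0, 1.0)
    return SpectralDistribution(w, np.ones_like(w), "absolute")
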