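import numpy as np
import pytest

from pamrm.chem import AcylChain
from pamrm.database import ChainSpace
from pamrm.spectra import Chromatogram, EPISpectrum


@pytest.fixture
def panel_space():
    return ChainSpace.default_panel()


@pytest.fixture
def worked_epi_spectrum():
    """The published worked example: a PA 34:2 EPI spectrum with four
    observed carboxylate ions and intensity order I253 > I255 = I281 > I279."""
    return EPISpectrum(
        precursor_mz=671.46,
        retention_time_min=9.45,
        mz=np.array([253.42, 255.28, 279.25, 281.27]),
        intensities=np.array([100.0, 60.0, 30.0, 60.0]),
    )


def gaussian_chromatogram(
    amplitude=1000.0,
    sigma=0.05,
    apex=9.45,
    t0=8.5,
    t1=10.5,
    dt=0.002,
    baseline=0.0,
    q1=671.46,
    q3=253.21,
):
    times = np.arange(t0, t1, dt)
    intensities = baseline + amplitude * np.exp(-0.5 * ((times - apex) / sigma) ** 2)
    return Chromatogram(q1, q3, times, intensities)


@pytest.fixture
def gaussian_xic():
    return gaussian_chromatogram()
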