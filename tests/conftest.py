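import numpy as np
import pytest

from hyalkit import gel, nanopore


@pytest.fixture(scope="session")
def wide_ladder():
    """Synthetic ladder calibration spanning 10-50000 kDa over 700 px."""
    mws = np.geomspace(50000.0, 10.0, 8)
    px = np.linspace(30.0, 730.0, 8)
    return gel.fit_gel_calibration(list(zip(px, mws)))


@pytest.fixture(scope="session")
def ecd_standards():
    """Noiseless power-law standards: ECD = 0.2 fC per kDa at the 7 MWs."""
    return [(m, 0.2 * m / 1000.0) for m in [54, 81, 130, 237, 545, 1076, 2384]]


@pytest.fixture(scope="session")
def ecd_calibration(ecd_standards):
    return nanopore.fit_ecd_calibration(ecd_standards)
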