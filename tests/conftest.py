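import numpy as np
import pytest

import radiokin as rk


@pytest.fixture(scope="session")
def h5():
    return rk.PEPTIDE_TABLE["H5"]


@pytest.fixture(scope="session")
def h9():
    return rk.PEPTIDE_TABLE["H9"]


@pytest.fixture(scope="session")
def pulse_tc():
    """Default pulse: 4.5 Gy instantaneous, 1 mM KSCN, N2O-saturated, 10 us."""
    return rk.simulate_pulse()


@pytest.fixture(scope="session")
def gamma_h5():
    """Default continuous irradiation of H5: 0.1 wt%, 10 kGy/h to 15 kGy."""
    return rk.simulate_gamma(rk.PEPTIDE_TABLE["H5"])
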