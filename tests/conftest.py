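import pytest

from qsarx.io import load_eis_table, load_high_efficiency_table, load_polarization_table


@pytest.fixture(scope="session")
def high_efficiency_table():
    """Ten-drug reference descriptor table (pKa, orbitals, omega, delta_n, IE%)."""
    return load_high_efficiency_table()


@pytest.fixture(scope="session")
def eis_table():
    """Lidocaine EIS circuit parameters, blank at 0 ppm."""
    return load_eis_table()


@pytest.fixture(scope="session")
def polarization_table():
    """Lidocaine Tafel parameters, blank at 0 ppm."""
    return load_polarization_table()
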