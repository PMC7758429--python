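import numpy as np
import pytest

from xcquad.fixtures import fixture_system, random_density


@pytest.fixture(scope="session")
def h2_sto():
    return fixture_system("H2", "sto-min")


@pytest.fixture(scope="session")
def heh_sp():
    return fixture_system("HeH", "s+p")


@pytest.fixture(scope="session")
def triatomic_sto():
    return fixture_system("triatomic", "sto-min")


@pytest.fixture(scope="session")
def h2_density(h2_sto):
    atoms, basis = h2_sto
    return random_density(atoms, basis, 2, seed=7)


@pytest.fixture(scope="session")
def heh_density_fg(heh_sp):
    atoms, basis = heh_sp
    return random_density(atoms, basis, 4, seed=3, grid_spec="FG")


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
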