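import numpy as np
import pytest

from nanosorb.forcefield import zns_table1_forcefield
from nanosorb.structures import LatticeSpec, build_unit_cell, derive_topology


@pytest.fixture(scope="session")
def lattice():
    return LatticeSpec()


@pytest.fixture(scope="session")
def unit_cell(lattice):
    return build_unit_cell(lattice)


@pytest.fixture(scope="session")
def unit_cell_topology(unit_cell):
    return derive_topology(unit_cell, 2.9)


@pytest.fixture(scope="session")
def table1_ff():
    return zns_table1_forcefield()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
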