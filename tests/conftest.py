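import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fcdg.fixtures import make_fixture_molecule, molecule_from_smiles

ETHANE_SDF = """ethane
  test

  8  7  0  0  0  0  0  0  0  0999 V2000
   -0.7560    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7560    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1404    0.6586    0.7845 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1404    0.3501   -0.9626 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1405   -1.0087    0.1781 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1404   -0.3501    0.9626 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1405    1.0087   -0.1781 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1404   -0.6586   -0.7845 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  2  6  1  0
  2  7  1  0
  2  8  1  0
M  END
"""


@pytest.fixture(scope="session")
def ethane_sdf() -> str:
    return ETHANE_SDF


@pytest.fixture(scope="session")
def butanol():
    """Butan-2-ol: exactly one stereocenter (C2)."""
    return molecule_from_smiles("CC(O)CC", seed=3)


@pytest.fixture(scope="session")
def bicyclic_cis():
    return make_fixture_molecule("bicyclic", 4, fusion="cis", seed=7)


@pytest.fixture(scope="session")
def bicyclic_trans():
    return make_fixture_molecule("bicyclic", 4, fusion="trans", seed=7)


@pytest.fixture(scope="session")
def macrocycle():
    return make_fixture_molecule("macrocycle", 4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
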