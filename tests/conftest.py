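import numpy as np
import pytest

from consensus_vs import chem_core
from consensus_vs.docking_post import COLCHICINE_SMILES


@pytest.fixture
def water():
    return chem_core.parse_smiles("O", "water")


@pytest.fixture
def benzene():
    return chem_core.parse_smiles("c1ccccc1", "benzene")


@pytest.fixture
def methane():
    return chem_core.parse_smiles("C", "methane")


@pytest.fixture
def ethanol():
    return chem_core.parse_smiles("CCO", "ethanol")


@pytest.fixture
def colchicine():
    return chem_core.parse_smiles(COLCHICINE_SMILES, "colchicine")


SMALL_LIBRARY_SMILES = [
    "c1ccccc1O", "c1ccccc1N", "Cc1ccncc1", "COc1ccccc1", "c1ccc2ccccc2c1",
    "CCc1ccccc1", "Oc1ccc(Cl)cc1", "Nc1ccc(C)cc1", "c1ccsc1", "CCOc1ccccn1",
    "CC(C)c1ccccc1", "OCc1ccco1", "CCCCO", "CC(=O)Nc1ccccc1", "FC(F)(F)c1ccccc1",
]


@pytest.fixture
def small_library():
    return [
        chem_core.parse_smiles(s, f"M-{i:02d}")
        for i, s in enumerate(SMALL_LIBRARY_SMILES)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
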