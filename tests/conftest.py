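import numpy as np
import pytest

from loxqsar.compounds import build_compound_table, embed_3d
from loxqsar.synthetic import gen_toy_molecules


@pytest.fixture(scope="session")
def records():
    return build_compound_table()


@pytest.fixture(scope="session")
def by_no(records):
    return {r.no: r for r in records}


@pytest.fixture(scope="session")
def embedded(by_no):
    """Low-energy 3D structures of the compounds the tests interrogate."""
    return {
        no: embed_3d(by_no[no].smiles, seed=1) for no in (2, 5, 7, 8, 15)
    }


@pytest.fixture(scope="session")
def toys():
    return gen_toy_molecules()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
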