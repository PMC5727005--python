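import numpy as np
import pytest

from isoswap import fixtures as fx
from isoswap.fragmenter import fragment_molecule


@pytest.fixture
def benzene():
    return fx.make_ligand("benzene")


@pytest.fixture
def morpholine():
    return fx.make_ligand("morpholine")


@pytest.fixture
def biphenyl():
    return fx.make_ligand("biphenyl")


@pytest.fixture
def ethylbenzene():
    return fx.make_ligand("ethylbenzene")


@pytest.fixture
def murf_mock():
    return fx.make_ligand("murf_mock")


@pytest.fixture
def complex_pair():
    """Congruent-pocket complex pair with an exactly coincident planted
    benzene/benzene fragment pair."""
    return fx.make_complex_pair(11, planted_overlap=0.0)


@pytest.fixture
def all_template_molecules():
    return {name: fx.make_ligand(name) for name in fx.TEMPLATES}


@pytest.fixture
def benzene_fragment(biphenyl):
    return fragment_molecule(biphenyl)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
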