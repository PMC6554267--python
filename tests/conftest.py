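import pytest

from macroconf import fixtures
from macroconf.chemgraph import MolecularGraph
from macroconf.ffmin import ForceFieldEngine
from macroconf.search import memory_free_start


@pytest.fixture(scope="session")
def cyclohexane():
    return fixtures.make_cycloalkane(6)


@pytest.fixture(scope="session")
def cyclodecane():
    return fixtures.make_cycloalkane(10)


@pytest.fixture(scope="session")
def decalin():
    return MolecularGraph.from_smiles(fixtures.DECALIN_SMILES)


@pytest.fixture(scope="session")
def benzene():
    return MolecularGraph.from_smiles(fixtures.BENZENE_SMILES)


@pytest.fixture(scope="session")
def tetracycline():
    return MolecularGraph.from_smiles(fixtures.TETRACYCLINE_SMILES)


@pytest.fixture(scope="session")
def aba_like():
    return fixtures.aba_like_peptide()


@pytest.fixture(scope="session")
def sfti_like():
    return fixtures.trypsin_inhibitor_like_peptide()


@pytest.fixture(scope="session")
def hexapeptide():
    return fixtures.simple_peptide(6)


@pytest.fixture(scope="session")
def cyclohexane_start(cyclohexane):
    return memory_free_start(cyclohexane, seed=1)


@pytest.fixture(scope="session")
def cyclohexane_engine(cyclohexane):
    return ForceFieldEngine(cyclohexane)


@pytest.fixture(scope="session")
def cyclodecane_start(cyclodecane):
    return memory_free_start(cyclodecane, seed=1)


@pytest.fixture(scope="session")
def cyclodecane_engine(cyclodecane):
    return ForceFieldEngine(cyclodecane)
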