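import pytest

from mitokit.seqcore import Parameters
from mitokit.synthetic import make_toy_organelles


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def toy():
    """Default toy organelle dataset: (mito, plastid, feats, truth), seed 1."""
    return make_toy_organelles(seed=1)


@pytest.fixture(scope="session")
def toy_mito(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[3]
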