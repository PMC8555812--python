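import pytest

from codonqubo.codon_tables import Parameters, load_codon_table
from codonqubo.fixtures import uniform_table


@pytest.fixture(scope="session")
def ecoli():
    return load_codon_table("e_coli")


@pytest.fixture(scope="session")
def uniform():
    return uniform_table()


@pytest.fixture
def defaults():
    return Parameters()
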