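import pytest

from rdgnscreen import fixtures


@pytest.fixture(scope="session")
def ey_table():
    return fixtures.load_ey_network()


@pytest.fixture(scope="session")
def toy_table():
    return fixtures.load_toy_network()


@pytest.fixture(scope="session")
def pax6_table():
    return fixtures.load_pax6_expression()


@pytest.fixture(scope="session")
def candidate_table():
    return fixtures.load_candidate_genes()
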