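import pytest

from delphicos import delphi_data as dd


@pytest.fixture(scope="session")
def table4():
    """(registry, decision) transcription of the published selection table."""
    return dd.load_paper_fixture("table4")


@pytest.fixture(scope="session")
def registry(table4):
    return table4[0]


@pytest.fixture(scope="session")
def decision(table4):
    return table4[1]


@pytest.fixture(scope="session")
def table1():
    return dd.load_paper_fixture("table1")


@pytest.fixture(scope="session")
def panel():
    return dd.load_paper_fixture("table3")


@pytest.fixture(scope="session")
def roster(panel):
    return panel.to_roster()


@pytest.fixture(scope="session")
def table5():
    return dd.load_paper_fixture("table5")
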