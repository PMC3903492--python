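import pytest

from sc2flux import datasets


@pytest.fixture(scope="session")
def table2():
    return datasets.fixture_table2()


@pytest.fixture(scope="session")
def transport_states():
    return datasets.fixture_transport_states()
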