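import pytest

from fullersense import paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture(scope="session")
def bundles(fixtures):
    return fixtures["bundles"]
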