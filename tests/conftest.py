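import pytest

from muscle_logic import build_fixture, classify


@pytest.fixture(scope="session")
def fixture_onto():
    return build_fixture()


@pytest.fixture(scope="session")
def fixture_sat(fixture_onto):
    return classify(fixture_onto)
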