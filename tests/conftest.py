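import pytest

from swapmeta import build_fixture, packaged_constraints, packaged_fixture


@pytest.fixture(scope="session")
def constraints():
    return packaged_constraints()


@pytest.fixture(scope="session")
def fixture_rows():
    """The packaged 230-row reconstructed dataset."""
    return packaged_fixture()


@pytest.fixture(scope="session")
def rebuilt_rows(constraints):
    """The dataset rebuilt from constraints at seed 1 (as packaged)."""
    return build_fixture(constraints, seed=1)
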