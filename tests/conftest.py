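import pytest

from grindex import make_fixture_cohort, load_fixture_expected


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_expected():
    return load_fixture_expected()
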