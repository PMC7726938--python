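import pytest

from pmmb_impact import default_parameters, default_rules, paper_fixture


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def fixture():
    """(schedule, roster, params, payroll rules) under the study conditions."""
    return paper_fixture()


@pytest.fixture(scope="session")
def schedule(fixture):
    return fixture[0]


@pytest.fixture(scope="session")
def roster(fixture):
    return fixture[1]
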