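import pytest
from hypothesis import settings

import riskfuse as rf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bioassays():
    return rf.load_fixture("animal_bioassays")


@pytest.fixture(scope="session")
def human_studies():
    return rf.load_fixture("human_studies")


@pytest.fixture(scope="session")
def meta_inputs():
    return rf.load_fixture("meta_inputs")


@pytest.fixture(scope="session")
def table6():
    return rf.load_fixture("table6")


@pytest.fixture(scope="session")
def nikula_fit(bioassays):
    return rf.fit_multistage(bioassays["nikula"], 2)
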