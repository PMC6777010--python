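import logging

import pytest
from hypothesis import HealthCheck, settings

from ampinfer import datafiles, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# inference logs progress at INFO; keep test output quiet
logging.getLogger("ampinfer").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fig1():
    """The 30-gene walkthrough scenario."""
    return simulate.figure1_fixture()


@pytest.fixture(scope="session")
def hg38_subset():
    return datafiles.packaged_genome()


@pytest.fixture(scope="session")
def f1_panel():
    return datafiles.packaged_panel()


@pytest.fixture(scope="session")
def census():
    return datafiles.packaged_census()
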