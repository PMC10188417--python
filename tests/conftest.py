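import logging

import pytest
from hypothesis import settings

from osteoburden import FractureBurdenModel, load_country_params

logging.getLogger("osteoburden").setLevel(logging.ERROR)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_params():
    return {p.country_code: p for p in load_country_params()}


@pytest.fixture(scope="session")
def fitted():
    """Model calibrated to the bundled eight-country inputs."""
    return FractureBurdenModel.from_fixtures().fit()


@pytest.fixture(scope="session")
def scenario_results(fitted):
    """Default scenario grid (each lever at 10/50/100%) on the fixtures."""
    return fitted.run_scenarios()
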