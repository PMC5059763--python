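import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_hydride_warning(caplog):
    # the x > x_max warning fires on nearly every long simulation; keep the
    # test output readable but still assert on it via caplog where needed
    logging.getLogger("bioprotonic.dynamics").setLevel(logging.ERROR)
    yield
    logging.getLogger("bioprotonic.dynamics").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def ga_system_protocol():
    from bioprotonic import condition_config

    return condition_config("slb_gA")


@pytest.fixture(scope="session")
def alm_system_protocol():
    from bioprotonic import condition_config

    return condition_config("slb_alm")


@pytest.fixture(scope="session")
def slb_system_protocol():
    from bioprotonic import condition_config

    return condition_config("slb")
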