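import pytest
from hypothesis import HealthCheck, settings

from varanosize.io import (
    bundled_fossils,
    bundled_sizes,
    bundled_specimens,
    default_group_config,
    load_bundled_fixture,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specimens():
    return bundled_specimens()


@pytest.fixture(scope="session")
def sizes():
    return bundled_sizes()


@pytest.fixture(scope="session")
def fossils():
    return bundled_fossils()


@pytest.fixture(scope="session")
def group_config():
    return default_group_config()


@pytest.fixture(scope="session")
def reference_estimates():
    return load_bundled_fixture("reference_estimates")
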