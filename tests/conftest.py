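import logging

import pytest
from hypothesis import HealthCheck, settings

import paritymeta as pm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the fixture's open-ended top categories routinely lack bounded neighbours;
# silence the per-call warnings during tests
logging.getLogger("paritymeta").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reports():
    return pm.load_fixture()


@pytest.fixture(scope="session")
def by_id(reports):
    return {r.report_id: r for r in reports}


@pytest.fixture(scope="session")
def parous_effects(reports):
    """Default (shared-reference corrected) parous-vs-nulliparous effects."""
    return [pm.parous_contrast(r) for r in reports]
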