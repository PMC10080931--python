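import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_harmonization_logs():
    """Keep per-replicate INFO chatter out of simulation-heavy tests."""
    logging.getLogger("mrpipe").setLevel(logging.WARNING)
    yield
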