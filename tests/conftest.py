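from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_signatures():
    from algc4.classify import load_signatures

    return load_signatures()


@pytest.fixture(scope="session")
def site_spec():
    from algc4.classify import DiagnosticSiteSpec

    return DiagnosticSiteSpec()
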