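import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pipeline():
    """The default three-stage scorer (built once; models are immutable)."""
    from fuzzrula.rula import RulaPipeline

    return RulaPipeline.from_config()
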