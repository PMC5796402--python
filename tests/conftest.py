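import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rich_ctx():
    from helpers import rich_context

    return rich_context()


@pytest.fixture()
def bundle_world():
    """Registry, document bundle and contexts of the worked example."""
    from annolink.fixtures import worked_example_bundle

    return worked_example_bundle()
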