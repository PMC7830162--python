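import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_proteome():
    """The default synthetic benchmark proteome (seed 42, 20 per class)."""
    from phazscan.synthetic import GeneratorConfig, generate_proteome

    return generate_proteome(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def default_screen(default_proteome):
    from phazscan.screen import screen_proteome

    reports, summary = screen_proteome(
        default_proteome.proteins,
        default_proteome.sp_calls,
        default_proteome.domain_hits,
    )
    return reports, summary
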