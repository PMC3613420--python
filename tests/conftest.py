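import pytest
from hypothesis import HealthCheck, settings

# Derandomized so the suite is reproducible run-to-run.
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_proteome():
    """A 120-protein synthetic proteome shared by read-only tests."""
    from cpcargo.simulate import SimulationConfig, generate_proteome

    config = SimulationConfig(n_proteins=120, seed=11)
    records, annotations, truth = generate_proteome(config)
    return config, records, annotations, truth
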