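import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def shared_dataset():
    """Three loci with suppression shared across the Galloanserae (90 My)."""
    from zwevo import simdata

    cfg = simdata.SimulationConfig(
        n_loci=3, cds_length=600, seed=7,
        suppression_times={"Gg": 90e6, "Mg": 90e6, "Ap": 90e6},
    )
    return simdata.simulate_gametolog_history(cfg)
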