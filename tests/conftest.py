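import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic dataset shared across tests."""
    from atacdyn.simulate import SimConfig, default_samples, simulate_regions

    cfg = SimConfig(
        seed=42,
        regions_per_class=20,
        chromosomes=(("chr1", 1_200_000),),
        samples=default_samples(2),
        baseline_mean=60.0,
    )
    regions, truths = simulate_regions(cfg)
    return cfg, regions, truths
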