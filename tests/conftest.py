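import pytest
from hypothesis import HealthCheck, settings

import pirnaforge as pf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Reduced cohort for fast unit tests (60+15 loci on a 40 kb genome)."""
    config = pf.scaled_config(seed=11)
    genome, loci, truth = pf.generate_genome(config)
    return genome, loci, truth


@pytest.fixture(scope="session")
def default_sim():
    """Full default study conditions, fixed seed (used end-to-end)."""
    config = pf.SimConfig(seed=7)
    genome, loci, truth = pf.generate_genome(config)
    return genome, loci, truth
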