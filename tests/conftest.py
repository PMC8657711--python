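import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def presets():
    from lymphsig import generate_signature_set
    return generate_signature_set()


@pytest.fixture(scope="session")
def small_cohort():
    """A small end-to-end synthetic study shared across tests."""
    from lymphsig import SyntheticConfig, generate_cohort
    config = SyntheticConfig(
        n_samples_per_group={"FL-like": 8, "CLL-like": 8},
        mutations_per_sample=150, mutation_dispersion=None,
        contig_lengths=[80_000, 80_000], compartment_tile=5_000,
        seed=11)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
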