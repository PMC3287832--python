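import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bnsnp import SimConfig, generate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A compact replicate study shared by read-only tests."""
    cfg = SimConfig(n_individuals=150, n_snps=30, n_causal=9,
                    n_replicates=4, seed=11)
    return cfg, generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
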