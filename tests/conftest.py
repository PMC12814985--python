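import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_genotypes():
    """300 samples x 20 SNPs with mild AR(1) LD, the default study scale."""
    from astwas.simulate import simulate_genotypes

    return simulate_genotypes(300, 20, (0.05, 0.5), 0.2, seed=11)
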