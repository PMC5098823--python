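import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome():
    from parspipe.synthetic_data import gen_genome

    genome, _ = gen_genome(10_000, gc=0.5, seed=7, oric=4_000)
    return genome
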