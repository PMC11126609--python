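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


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fully featured cohort shared by read-only tests."""
    from mammoeval.synthetic import SynthConfig, generate_cohort

    config = SynthConfig(n_cases=24, n_normals=12, seed=123,
                         saliency_shape=(92, 60))
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
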