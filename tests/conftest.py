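import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoseries.phantom import PhantomConfig, generate_cohort
from thermoseries.pipeline import cohort_tensor

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort_tensor():
    """Feature tensor of the full default phantom cohort (25+25 subjects)."""
    cfg = PhantomConfig(seed=11)
    return cohort_tensor(generate_cohort(cfg))


@pytest.fixture(scope="session")
def small_cohort_tensor():
    """Reduced cohort for fast classifier tests (8+8 subjects, 64px grid)."""
    cfg = PhantomConfig(grid_size=64, n_per_class=8, seed=7)
    return cohort_tensor(generate_cohort(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
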