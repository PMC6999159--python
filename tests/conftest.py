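import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfnet import SyntheticConfig, generate_synthetic, run_comparison_study
from cfnet.protocols import synthetic_study_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def study_config():
    return synthetic_study_config()


@pytest.fixture(scope="session")
def synth_dataset():
    """Default-geometry dataset used across simulator/protocol tests."""
    return generate_synthetic(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap two-class dataset for protocol unit tests."""
    return generate_synthetic(
        SyntheticConfig(n_classes=2, clusters_per_class=2, samples_per_class=16, seed=7)
    )


@pytest.fixture(scope="session")
def comparison_study():
    """The full 5-seed CFN-vs-baselines study (shared by the heavy tests)."""
    return run_comparison_study()
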