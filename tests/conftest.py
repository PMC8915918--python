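import numpy as np
import pytest

from acutoxmap.hitcalls import apply_burst_filter
from acutoxmap.simulate import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast unit tests."""
    return GeneratorConfig(
        n_clusters=12,
        chems_per_cluster=(5, 9),
        n_background_chemicals=10,
        F=128,
        n_assays=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_study_burst(small_study):
    chemicals, fps, assays, truth = small_study
    return chemicals, fps, apply_burst_filter(assays, chemicals), truth


@pytest.fixture(scope="session")
def default_study():
    """The generator's default study conditions (seed-fixed)."""
    return generate_study(GeneratorConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
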