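import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miaqsar import CanvasSpec, ElementPropertyTable, GeneratorConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def props():
    return ElementPropertyTable.default()


@pytest.fixture(scope="session")
def canvas():
    return CanvasSpec()


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic congeneric series shared across tests (seed-fixed)."""
    ds = generate_dataset(GeneratorConfig(n_samples=16, noise_sd=0.1, seed=42))
    y = np.array([a.pki for a in ds.activities])
    return ds, y


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
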