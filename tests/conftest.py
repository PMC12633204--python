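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

from foodreadout import LibraryConfig, SynthConfig, learn_library, simulate_reference


@pytest.fixture(scope="session")
def reference_dataset():
    """One standard synthetic reference-food dataset, shared across tests."""
    return simulate_reference(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def learned_library(reference_dataset):
    table, ontology, spectra, _ = reference_dataset
    return learn_library(table, ontology, spectra, LibraryConfig(vip_threshold=1.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
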