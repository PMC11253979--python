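import pytest

from circakidney.scenario import generate_fixtures
from circakidney.transport import default_initial_model, load_default_model


@pytest.fixture(scope="session")
def model():
    """The calibrated parameter set shipped with the package."""
    return load_default_model()


@pytest.fixture(scope="session")
def initial_model():
    return default_initial_model()


@pytest.fixture(scope="session")
def fixture_set():
    """Seeded perturbed parameter sets and surrogate registries."""
    return generate_fixtures(seed=20240717, n_models=200, n_surrogates=2)
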