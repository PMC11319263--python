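import numpy as np
import pytest

from cgmgp.growth_model import GenotypeParameters, ModelConstants
from cgmgp.synthetic_data import TrialDesign, generate_dataset, simulate_weather


@pytest.fixture(scope="session")
def mid_params():
    """A parameter set near the middle of every admissible interval."""
    return GenotypeParameters(
        epsib=5.5, plasto_init=35.0, phyllo_init=38.0, ligulo_init=35.0,
        ict=1.2, mgr_init=10.0, ll_to_il=0.15, slap=0.05,
    )


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def constant_weather():
    """45 deterministic days: 30/23 degC day/night, 10 MJ m-2 d-1."""
    return simulate_weather(45, temp_jitter=0.0, radiation_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_weather():
    return simulate_weather(45, seed=3)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study shared across test modules."""
    return generate_dataset(TrialDesign(n_genotypes=60, n_markers=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
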