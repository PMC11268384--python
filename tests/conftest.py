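import pytest

from nsaidburden.config import EngineConfig
from nsaidburden.datasets import england_population, england_prevalence
from nsaidburden.models import build_all_models
from nsaidburden.psa import run_psa
from nsaidburden.synthetic import generate_parameter_tables


@pytest.fixture(scope="session")
def engine():
    return EngineConfig()


@pytest.fixture(scope="session")
def pset():
    """One paper-magnitude synthetic parameter set shared across tests."""
    return generate_parameter_tables(seed=101, preset="paper_magnitude")


@pytest.fixture(scope="session")
def models(pset):
    return build_all_models(pset.tables)


@pytest.fixture(scope="session")
def draws(models, engine):
    """A modest shared PSA run (400 samples)."""
    return run_psa(models, 400, seed=11, config=engine)


@pytest.fixture(scope="session")
def prevalence():
    return england_prevalence()


@pytest.fixture(scope="session")
def population():
    return england_population()
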