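import pytest

from mirseed.preprocess import PreprocessParams
from mirseed.simulate import SimulationConfig, build_references, simulate_library


@pytest.fixture(scope="session")
def sim_config():
    """Small, fast study-condition config used across tests (fixed seed)."""
    return SimulationConfig(seed=7, n_reads=12_000, n_families=10)


@pytest.fixture(scope="session")
def sim_refs(sim_config):
    return build_references(sim_config)


@pytest.fixture(scope="session")
def sim_library(sim_config, sim_refs):
    reads, manifest = simulate_library(sim_config, sim_refs)
    return reads, manifest


@pytest.fixture(scope="session")
def preprocess_params(sim_config):
    return PreprocessParams(adapter=sim_config.adapter)
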