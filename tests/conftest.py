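import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from erfminer.simulate import (
    SimConfig,
    make_annotation_fixture,
    make_codon_fixture,
    make_expression_fixture,
    make_family_fixture,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def family_fixture(sim_config):
    return make_family_fixture(sim_config)


@pytest.fixture(scope="session")
def annotation_fixture(sim_config):
    return make_annotation_fixture(sim_config)


@pytest.fixture(scope="session")
def codon_fixture(sim_config):
    return make_codon_fixture(sim_config)


@pytest.fixture(scope="session")
def expression_fixture(sim_config):
    return make_expression_fixture(sim_config)
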