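import pytest

from isotrx import simulate


@pytest.fixture(scope="session")
def sim_cfg():
    return simulate.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def reference(sim_cfg):
    return simulate.simulate_reference(sim_cfg)


@pytest.fixture(scope="session")
def annotation(reference):
    return reference[0]


@pytest.fixture(scope="session")
def fusion_data(annotation, sim_cfg):
    return simulate.simulate_fusion_alignments(annotation, sim_cfg)


@pytest.fixture(scope="session")
def expression_data(annotation, sim_cfg):
    return simulate.simulate_expression_with_targets(annotation, sim_cfg)


@pytest.fixture(scope="session")
def presence_data(annotation, sim_cfg):
    return simulate.simulate_presence_catalogs(annotation, sim_cfg)
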