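import pytest

from isofrag.masses import ResidueTable, default_losses
from isofrag.simulate import default_paper_scenario, simulate


@pytest.fixture(scope="session")
def table():
    return ResidueTable.default()


@pytest.fixture(scope="session")
def losses():
    return default_losses()


@pytest.fixture(scope="session")
def scenario_config():
    # building the three fragment catalogues dominates the cost; share it
    return default_paper_scenario(seed=20)


@pytest.fixture(scope="session")
def scenario_run(scenario_config):
    return simulate(scenario_config)
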