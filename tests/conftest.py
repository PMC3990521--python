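import pytest

from occupeak.synthetic import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """One default-condition synthetic study shared by read-only tests."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)
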