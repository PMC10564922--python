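import pytest

from cernaforge.io_formats import load_table3
from cernaforge.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study shared across tests (fixed seed)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def table3_rows():
    return load_table3()
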