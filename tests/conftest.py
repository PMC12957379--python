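import pytest

from dropmix import FlowConfig, TransportProperties, preset_device
from dropmix.device import REFERENCE_FLOWS


@pytest.fixture(scope="session")
def dg300():
    return preset_device("DG300-Y")


@pytest.fixture(scope="session")
def dg250():
    return preset_device("DG250-Y")


@pytest.fixture(scope="session")
def dg300_flows():
    return REFERENCE_FLOWS["DG300-Y"]


@pytest.fixture(scope="session")
def dg250_flows():
    return REFERENCE_FLOWS["DG250-Y"]


@pytest.fixture(scope="session")
def nadh_props():
    """NADH transport properties in the PEG 3350 mother liquor."""
    return TransportProperties()


@pytest.fixture(scope="session")
def slow_flows():
    """Aqueous flows slow enough for equimolarity inside the mixer channel
    while keeping the axial Péclet number above the parabolized-model
    threshold."""
    return FlowConfig(q_x=0.05, q_s=0.04, q_o=1.0)
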