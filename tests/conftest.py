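import pytest

from csfcircuit import ModelParameters, ShuntSpec, SimulationSettings, simulate


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def normal_trace(params):
    """Pulsatile healthy-baseline run, shared across tests."""
    return simulate(params, ShuntSpec.absent(), SimulationSettings())


# Steady node pressures solved independently (exact symbolic solve of the
# conducting-diode nodal system with the source at its 16 kPa offset).
DC_ICP = {
    (1.0, None): 706.0900,
    (5.0, None): 2492.2118,
    (10.0, None): 3644.6469,
    (10.0, 1.11111): 706.0895,
    (10.0, 1.25): 775.5696,
    (10.0, 1.5): 892.6911,
    (10.0, 2.0): 1100.4127,
    (10.0, 2.5): 1278.9768,
    (10.0, 3.0): 1434.1201,
    (10.0, 100.0): 3483.5619,
}
DC_NORMAL_NODES = {"P_a": 7696.3813, "P_c": 4236.5402,
                   "P_v": 2033.5393, "P_ic": 706.0900}
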