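import pytest
from hypothesis import HealthCheck, settings

import kirpop as kp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ethanol_set() -> kp.ParameterSet:
    return kp.load_builtin("table1_ethanol")


@pytest.fixture(scope="session")
def nicotine_set() -> kp.ParameterSet:
    return kp.load_builtin("table2_nicotine")


@pytest.fixture(scope="session")
def eth_const(ethanol_set) -> kp.ModelParams:
    return ethanol_set.component("CONST")


@pytest.fixture(scope="session")
def eth_ach(ethanol_set) -> kp.ModelParams:
    return ethanol_set.component("ACH")


@pytest.fixture(scope="session")
def nic_const(nicotine_set) -> kp.ModelParams:
    return nicotine_set.component("CONST")


@pytest.fixture(scope="session")
def nic_ach(nicotine_set) -> kp.ModelParams:
    return nicotine_set.component("ACH")


@pytest.fixture(scope="session")
def all_components(eth_const, eth_ach, nic_const, nic_ach):
    return {
        "ethanol/CONST": eth_const,
        "ethanol/ACH": eth_ach,
        "nicotine/CONST": nic_const,
        "nicotine/ACH": nic_ach,
    }
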