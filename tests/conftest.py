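import numpy as np
import pytest

from her2qsp import TumorGrowthModel
from her2qsp.protocols import XenograftProtocol, control_regimen

ALL_DRUGS = ["lapatinib", "pyrotinib", "capecitabine", "T-DM1", "T-DXd"]


@pytest.fixture(scope="session")
def skbr3_lap():
    """In vitro SKBR3 model carrying lapatinib."""
    return TumorGrowthModel.skbr3(drugs=["lapatinib"])


@pytest.fixture(scope="session")
def skbr3_lap_ss(skbr3_lap):
    return skbr3_lap.steady_state()


@pytest.fixture(scope="session")
def skbr3_vitro_full():
    """In vitro SKBR3 model carrying all five drug mechanisms."""
    return TumorGrowthModel.skbr3(drugs=ALL_DRUGS)


@pytest.fixture(scope="session")
def vivo_full():
    """In vivo SKBR3 model with embedded PK for all five drugs."""
    return TumorGrowthModel.skbr3(drugs=ALL_DRUGS, in_vivo=True)


@pytest.fixture(scope="session")
def vivo_control_62(vivo_full):
    """Vehicle-arm tumor growth over 62 days (shared across tests)."""
    return vivo_full.xenograft(control_regimen(), XenograftProtocol(follow_up_days=62))


@pytest.fixture(scope="session")
def vivo_control_20(vivo_control_62):
    return vivo_control_62[vivo_control_62["day"] <= 20.0].reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
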