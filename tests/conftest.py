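import numpy as np
import pytest

from recflip import CircuitParameters, default_dose_ladder


@pytest.fixture(scope="session")
def params() -> CircuitParameters:
    return CircuitParameters()


@pytest.fixture(scope="session")
def ladder() -> np.ndarray:
    return default_dose_ladder()


@pytest.fixture(scope="session")
def decoupled_params() -> CircuitParameters:
    """No resource competition, no complex chemistry, no flipping."""
    return CircuitParameters(w_G=0, w_R=0, w_I=0, k_on=0, V_on=0, V_off=0)
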