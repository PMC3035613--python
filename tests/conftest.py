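import numpy as np
import pytest

from notchfate import (
    DeltaNotchModel,
    oscillation_features,
    table1_parameters,
    table2_parameters,
)

BASELINE_WINDOW = (2000.0, 3000.0)


@pytest.fixture(scope="session")
def model_t2():
    return DeltaNotchModel(params=table2_parameters())


@pytest.fixture(scope="session")
def model_t1():
    return DeltaNotchModel(params=table1_parameters())


@pytest.fixture(scope="session")
def baseline_t2(model_t2):
    """Unperturbed 3,000 min run with the calibrated parameters."""
    return model_t2.simulate(3000.0)


@pytest.fixture(scope="session")
def baseline_t1(model_t1):
    return model_t1.simulate(3000.0)


@pytest.fixture(scope="session")
def baseline_features_t2(baseline_t2):
    return {
        "hes1": oscillation_features(baseline_t2, "hes1_prot_nuc", BASELINE_WINDOW),
        "mash1": oscillation_features(baseline_t2, "mash1_prot_nuc", BASELINE_WINDOW),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
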