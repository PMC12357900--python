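import numpy as np
import pytest

from nfkb_crosstalk import (BASAL_HIGH, BASAL_LOW, StimulusSpec,
                            apply_basal_activation, canonical_parameters,
                            simulate, steady_state)


@pytest.fixture(scope="session")
def params_low():
    return apply_basal_activation(canonical_parameters(), BASAL_LOW)


@pytest.fixture(scope="session")
def params_high():
    return apply_basal_activation(canonical_parameters(), BASAL_HIGH)


@pytest.fixture(scope="session")
def ss_low(params_low):
    return steady_state(params_low)


@pytest.fixture(scope="session")
def ss_high(params_high):
    return steady_state(params_high)


@pytest.fixture(scope="session")
def traj_low_cd40(params_low, ss_low):
    return simulate(params_low, ss_low, duration=1440.0,
                    stimulus=StimulusSpec(cd40_on=True), scenario="low_CD40")


@pytest.fixture(scope="session")
def traj_high_cd40(params_high, ss_high):
    return simulate(params_high, ss_high, duration=1440.0,
                    stimulus=StimulusSpec(cd40_on=True), scenario="high_CD40")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
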