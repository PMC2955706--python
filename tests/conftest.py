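import pytest

from chlamycycle.cycle_model import CycleParams


@pytest.fixture
def noiseless_params() -> CycleParams:
    """Model constants with every noise source switched off."""
    return CycleParams(cv_mu=0.0, cv_threshold=0.0, cv_measurement=0.0, v0_cv=0.0)


@pytest.fixture
def default_params() -> CycleParams:
    return CycleParams()
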