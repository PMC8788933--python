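import numpy as np
import pytest

from neurocost import biophys


@pytest.fixture(scope="session")
def calibrated_model():
    """Calibrated control-condition HH model (shared; calibration is
    deterministic but costs a few seconds)."""
    return biophys.calibrate_channels()


@pytest.fixture(scope="session")
def group_models(calibrated_model):
    return {g: biophys.group_params(calibrated_model, g) for g in biophys.GROUPS}


@pytest.fixture(scope="session")
def syn():
    return biophys.SynapticInput()


@pytest.fixture(scope="session")
def rheobases(group_models, syn):
    return {g: biophys.find_rheobase(m, syn) for g, m in group_models.items()}
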