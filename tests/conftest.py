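import numpy as np
import pytest

from oculomech import reference as ref
from oculomech.synthetic import default_geometry


@pytest.fixture(scope="session")
def region_models():
    """Reference second-order models for all six tissue regions."""
    return {r: ref.glaucoma_model(r) for r in ref.REGIONS}


@pytest.fixture(scope="session")
def anterior_model(region_models):
    return region_models["anterior"]


@pytest.fixture(scope="session")
def anterior_geometry():
    return default_geometry("anterior")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
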