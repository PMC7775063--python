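import numpy as np
import pytest

from saurogait.biomech import BiomechModel, TrajectoryParams, build_biomech_model
from saurogait.planar import PlanarModel, build_planar_model


@pytest.fixture(scope="session")
def planar_model() -> PlanarModel:
    return build_planar_model()


@pytest.fixture(scope="session")
def biomech_model() -> BiomechModel:
    return build_biomech_model()


@pytest.fixture(scope="session")
def trajectory() -> TrajectoryParams:
    return TrajectoryParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
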