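import numpy as np
import pytest

from canopyflow import AirProperties, CanopyLayer, FlowCondition, JetGeometry

# Laboratory drag campaign: (Lr, v*) -> (windward area s [m^2], force F [N])
LAB_CAMPAIGN = {
    (4.15, 4): (0.057, 0.97),
    (4.15, 8): (0.057, 2.96),
    (4.15, 12): (0.057, 4.98),
    (4.79, 4): (0.060, 0.94),
    (4.79, 8): (0.060, 2.63),
    (4.79, 12): (0.060, 4.49),
    (5.65, 4): (0.065, 0.88),
    (5.65, 8): (0.065, 2.35),
    (5.65, 12): (0.065, 4.11),
}

# Published attenuation factors for the same nine conditions [1/m]
REFERENCE_K = {
    (4.15, 4): 0.746,
    (4.15, 8): 1.159,
    (4.15, 12): 1.682,
    (4.79, 4): 0.874,
    (4.79, 8): 1.457,
    (4.79, 12): 2.014,
    (5.65, 4): 1.087,
    (5.65, 8): 1.824,
    (5.65, 12): 2.401,
}

# Published per-volume windward areas [m^2/m^3] per density
REFERENCE_T = {4.15: 2.353, 4.79: 2.480, 5.65: 2.673}

D_CANOPY = 0.9
D_PRIME = 0.3
JET_RADIUS = 0.16


@pytest.fixture
def air() -> AirProperties:
    return AirProperties(rho=1.29, c_d=1.0)


@pytest.fixture
def jet() -> JetGeometry:
    return JetGeometry(R=JET_RADIUS)


@pytest.fixture
def sparse_layer() -> CanopyLayer:
    return CanopyLayer(leaf_area_density=4.15, s0=0.057, D=D_CANOPY, D_prime=D_PRIME)


def make_layer(lr: float) -> CanopyLayer:
    s = LAB_CAMPAIGN[(lr, 4)][0]
    return CanopyLayer(leaf_area_density=lr, s0=s, D=D_CANOPY, D_prime=D_PRIME)


@pytest.fixture
def cond4() -> FlowCondition:
    return FlowCondition(4.0)


@pytest.fixture
def depth_grid() -> np.ndarray:
    return np.array([0.15, 0.30, 0.45, 0.60, 0.75, 0.90])
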