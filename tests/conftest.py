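import numpy as np
import pytest

from togglepop.models import PopulationSpec
from togglepop.params import MODIFIED, REFERENCE, ModelParams


@pytest.fixture
def reference() -> ModelParams:
    return REFERENCE


@pytest.fixture
def modified() -> ModelParams:
    return MODIFIED


@pytest.fixture
def spec_s1() -> PopulationSpec:
    return PopulationSpec("S", (1,))


@pytest.fixture
def spec_a1() -> PopulationSpec:
    return PopulationSpec("A", (1,))


@pytest.fixture
def spec_s11() -> PopulationSpec:
    return PopulationSpec("S", (1, 1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def fixed_point_oracle_s(params, max_iter=500, damping=0.5,
                         start=(30.0, 0.0, 3.0, 0.0)):
    """Independent scalar fixed-point oracle for a decoupled S toggle (d=0).

    Damped iteration on x = a1/(1+y^nY) + a3 g^nG/(1+g^nG),
    y = a2/(1+x^nX) + a4 r^nR/(1+r^nR), g = a5/(dg (1+y^nY)),
    r = a6/(dr (1+x^nX)).
    """
    p = params
    x, y, g, r = start
    for _ in range(max_iter):
        xn = p.gamma_x + p.a1 / (1 + y**p.nY) + p.a3 * g**p.nG / (1 + g**p.nG)
        yn = p.gamma_y + p.a2 / (1 + x**p.nX) + p.a4 * r**p.nR / (1 + r**p.nR)
        gn = (p.gamma_g + p.a5 / (1 + y**p.nY)) / p.delta_g
        rn = (p.gamma_r + p.a6 / (1 + x**p.nX)) / p.delta_r
        x = damping * x + (1 - damping) * xn
        y = damping * y + (1 - damping) * yn
        g = damping * g + (1 - damping) * gn
        r = damping * r + (1 - damping) * rn
    return x, y, g, r


def fixed_point_oracle_a(params, max_iter=500, damping=0.5,
                         start=(20.0, 0.0, 0.0)):
    """Independent fixed-point oracle for a decoupled A toggle (d=0)."""
    p = params
    x, y, r = start
    for _ in range(max_iter):
        xn = p.gamma_x + p.a1 / (1 + y**p.nY) + p.a4 * r**p.nR / (1 + r**p.nR)
        yn = p.gamma_y + p.a2 / (1 + x**p.nX)
        rn = (p.gamma_r + p.a6 / (1 + x**p.nX)) / p.delta_r
        x = damping * x + (1 - damping) * xn
        y = damping * y + (1 - damping) * yn
        r = damping * r + (1 - damping) * rn
    return x, y, r
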