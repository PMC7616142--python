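import numpy as np
import pytest

from mshell import ScenarioParams, undeformed_sphere


@pytest.fixture(scope="session")
def sphere201():
    return undeformed_sphere(n_grid=201)


@pytest.fixture(scope="session")
def grid201():
    return np.linspace(0.0, np.pi, 201)


@pytest.fixture
def fig5a_params():
    return ScenarioParams(kappa_p=1.0, kappa_b=-2.0, kappa_a=1.0, f_p=0.8,
                          f_a=1.0, s0=1.5, w=0.2, eps_h=0.15)


@pytest.fixture
def fig5d_params():
    return ScenarioParams(kappa_p=1.0, kappa_b=-8.5, kappa_a=1.0, f_p=0.8,
                          f_a=1.0, s0=1.5, w=0.5, eps_h=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(20211103)
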