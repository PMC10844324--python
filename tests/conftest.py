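import numpy as np
import pytest

from chronobind import DesignSpec, FitConfig, ObserverParams


@pytest.fixture
def default_params():
    """The study's printed baseline biases/noises."""
    return ObserverParams(b_A=-52.22, sigma_A=61.56, b_O=18.27, sigma_O=61.56)


@pytest.fixture
def zero_bias_params():
    """Unbiased observer, convenient for closed-form mean predictions."""
    return ObserverParams(b_A=0.0, sigma_A=61.56, b_O=0.0, sigma_O=61.56)


@pytest.fixture
def small_design():
    return DesignSpec(trials_per_condition=20, n_observers=1)


@pytest.fixture
def fast_cfg():
    """Cheap but valid fitting configuration for unit tests."""
    return FitConfig(n_mc=4_000, seed=0, grid_points=21, de_popsize=6,
                     de_maxiter=30, de_tol=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
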