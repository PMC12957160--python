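import numpy as np
import pytest

from fracalz.glsolver import SolverGrid
from fracalz.model import ModelParameters, TABLE1_PARAMS, TABLE1_STATE


@pytest.fixture
def table1():
    return TABLE1_PARAMS, TABLE1_STATE.copy()


@pytest.fixture
def short_grid():
    return SolverGrid(10.0, 50)


def linear_decay_params(rate: float = 1.0) -> ModelParameters:
    """Parameters that make the model exactly D^s F_N = -rate*F_N when
    started from (1, 0, 0, 0, 0): every coupling is switched off."""
    return ModelParameters(
        Pi_N=0.0, rho=0.0, alpha=0.0, phi1=rate, beta1=0.0, gamma=0.0,
        phi2=0.0, beta2=0.0, d_beta=1.0, kappa=0.0, beta3=0.0, d_mu=1.0, phi3=1.0,
    )


def random_admissible_params(rng: np.random.Generator) -> ModelParameters:
    """Random strictly-positive parameter draw for property tests."""
    draw = {name: float(rng.uniform(0.01, 2.0)) for name in ModelParameters.field_names()}
    return ModelParameters(**draw)
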