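import numpy as np
import pytest

import tfcircuit as tc


@pytest.fixture
def rng():
    return np.random.default_rng(20220831)


@pytest.fixture
def params2(rng):
    """A perturbed in-bounds 2-TF parameter set."""
    return tc.init_params(2, rng, perturb_sd=0.2)


@pytest.fixture
def constant_f_gene():
    """Single-gene circuit whose activation is identically 0.7 (all alphas
    equal), so its ODE is linear with a closed-form solution."""
    c = 0.7
    return tc.ModelParams(
        n=1,
        m=np.array([5e-3]),
        delta=np.array([2e-4]),
        s=np.array([5e-2]),
        gamma=np.array([5e-3]),
        x0=np.array([3.0]),
        y0=np.array([200.0]),
        k=np.array([[5e2]]),
        h=np.array([[2.0]]),
        alpha=np.full((1, 2), c),
        r=np.ones((1, 0)),
    ), c
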