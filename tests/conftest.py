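import numpy as np
import pytest

import carbontime as ct


@pytest.fixture(scope="session")
def estanzuela_models():
    return ct.estanzuela()


@pytest.fixture(scope="session")
def estanzuela_trajs(estanzuela_models):
    return {name: ct.simulate(m, 60.0, step=0.01)
            for name, m in estanzuela_models.items()}


@pytest.fixture()
def one_pool_decay():
    """S1-style single pool: C(t) = 6 e^{-0.01 t}, no inputs."""
    return ct.CompartmentalModel(B=[[-0.01]], u=[0.0], x0=[6.0], name="decay")


@pytest.fixture()
def chain_model():
    """Two-pool serial chain: all of pool 1's outflow feeds pool 2."""
    return ct.CompartmentalModel(B=[[-0.5, 0.0], [0.5, -0.05]],
                                 u=[1.0, 0.0], x0=[0.0, 0.0], name="chain")


def relative_gap(a, b, scale=1.0):
    """|a-b| over a floor-protected scale, for near-zero-safe comparisons."""
    return abs(a - b) / max(abs(a), abs(b), scale)
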