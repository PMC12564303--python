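import numpy as np
import pytest

from trispread import ModelParams, fixture_multiplex


@pytest.fixture(scope="session")
def triangle3():
    return fixture_multiplex("triangle3")


@pytest.fixture(scope="session")
def star5():
    return fixture_multiplex("star5")


@pytest.fixture(scope="session")
def path4():
    return fixture_multiplex("path4")


@pytest.fixture(scope="session")
def er300():
    return fixture_multiplex("er300")


@pytest.fixture(scope="session")
def ba300():
    return fixture_multiplex("ba300")


@pytest.fixture()
def default_params():
    return ModelParams(
        lambda_info=0.5, delta=0.3, eta=0.2, omega=0.3, theta=0.0, beta=0.16, mu=0.3, gamma=3.0
    )


def random_distribution(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """A random valid (n, 7) state distribution (rows on the simplex)."""
    x = rng.gamma(1.0, size=(n_nodes, 7))
    return x / x.sum(axis=1, keepdims=True)
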