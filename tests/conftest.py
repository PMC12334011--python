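import numpy as np
import pytest

from crimedyn.io import load_fixture_params, load_fixture_state
from crimedyn.model import TransitionParameters


@pytest.fixture(scope="session")
def black_men():
    return load_fixture_params("table5_black_men")


@pytest.fixture(scope="session")
def white_men():
    return load_fixture_params("table5_white_men")


@pytest.fixture(scope="session")
def black_men_initial():
    return load_fixture_state("table4_initial_black_men")


@pytest.fixture(scope="session")
def white_men_initial():
    return load_fixture_state("table4_initial_white_men")


def random_interior_params(rng: np.random.Generator,
                           eps: float = 0.01) -> TransitionParameters:
    """A random parameter draw with every free rate and stay in (eps, 1)."""
    while True:
        draw = rng.uniform(eps, 1 - eps, size=11)
        try:
            params = TransitionParameters.from_array(draw)
        except Exception:
            continue
        if params.is_interior(eps / 2):
            return params
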