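import numpy as np
import pytest

from hemefold.params import load_parameters
from hemefold.synthetic import ToySpec, make_ideal_heme, make_mini_globin


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def toy_b(params):
    """(native, extended) heme b mini-globin; treat as read-only."""
    return make_mini_globin(ToySpec(heme_type="b", seed=0), params=params)


@pytest.fixture(scope="session")
def toy_c(params):
    """(native, extended) heme c mini-globin; treat as read-only."""
    return make_mini_globin(ToySpec(heme_type="c", seed=0), params=params)


@pytest.fixture()
def ideal_heme_b(params):
    return make_ideal_heme("b", params)


@pytest.fixture()
def ideal_heme_c(params):
    return make_ideal_heme("c", params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def jiggled(state, rng, scale=0.01):
    """Fresh copy of a state with Gaussian-perturbed coordinates."""
    out = state.copy()
    x = out.get_coords()
    out.set_coords(x + scale * rng.standard_normal(x.shape))
    return out
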