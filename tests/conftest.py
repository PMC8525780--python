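import numpy as np
import pytest

from leafspec.synthetic import gen_aci_curve


@pytest.fixture
def leaf_traits():
    """A typical mid-canopy tropical leaf."""
    return {"Vcmax25": 60.0, "Jmax25": 110.0, "Rdark25": 0.9}


@pytest.fixture
def noiseless_curve(leaf_traits):
    return gen_aci_curve(leaf_traits, noise_sd=0.0, Tleaf=30.0, seed=0, leaf_id="clean")


@pytest.fixture
def noisy_curve(leaf_traits):
    return gen_aci_curve(leaf_traits, noise_sd=0.5, Tleaf=31.0, seed=1, leaf_id="noisy")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
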