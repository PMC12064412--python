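import numpy as np
import pytest

from protdyn.select import select
from protdyn.synthetic import make_toy_chain, sample_enm_gaussian


@pytest.fixture(scope="session")
def helix10():
    return make_toy_chain(10, "helix")


@pytest.fixture(scope="session")
def helix40():
    return make_toy_chain(40, "helix")


@pytest.fixture(scope="session")
def ca_mask10(helix10):
    return select(helix10, "name CA")


@pytest.fixture(scope="session")
def enm_ensemble(helix10):
    """A moderate-size ENM Gaussian ensemble with its exact covariance."""
    ens, gt = sample_enm_gaussian(helix10, n_frames=5000, seed=11)
    return ens, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
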