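import numpy as np
import pytest

from bodycomp.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def thigh_case():
    return generate_phantom(PhantomParams(region="thigh", imat_fraction=0.20, seed=7))


@pytest.fixture(scope="session")
def abdomen_case():
    return generate_phantom(PhantomParams(region="abdomen", imat_fraction=0.10, seed=11))


@pytest.fixture(scope="session")
def noiseless_thigh():
    return generate_phantom(
        PhantomParams(region="thigh", imat_fraction=0.20, noise_sd=0.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
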