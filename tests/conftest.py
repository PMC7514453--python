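import numpy as np
import pytest

import sgais as sg


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def conjugate_model():
    return sg.make_gaussian_mean_model()


@pytest.fixture(scope="session")
def conjugate_data(conjugate_model):
    return sg.simulate_dataset(conjugate_model, [0.7], 200, seed=1)


@pytest.fixture(scope="session")
def toy2_model():
    """2-parameter model (1 weight + intercept) with closed-form evidence."""
    return sg.make_linreg_model(n_features=1)


@pytest.fixture(scope="session")
def toy2_data(toy2_model):
    theta = sg.draw_true_parameters(toy2_model, seed=3)
    return sg.simulate_dataset(toy2_model, theta, 40, seed=4)
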