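import numpy as np
import pytest

from faceutil.gpor import GporHyperparams, OrdinalDataset, fit_gpor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_hyper():
    """R = 3 categories, unit noise, symmetric thresholds, 1-D inputs."""
    return GporHyperparams(eta=[1.0], sigma=1.0, b=[-1.0, 1.0])


@pytest.fixture
def small_model(simple_hyper):
    data = OrdinalDataset(x=[[-1.0], [0.0], [1.2]], y=[1, 2, 3], r=3)
    return fit_gpor(data, simple_hyper)


@pytest.fixture
def likert_hyper():
    """R = 5, the rating scale used throughout the full-scale simulations."""
    return GporHyperparams(
        eta=[0.5, 0.5, 0.5], sigma=1.0, b=[-1.5, -0.5, 0.5, 1.5]
    )
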