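import numpy as np
import pytest

from stiefnet import model, stiefel, vmf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_params(rng):
    """A small (n=3, p=2) model with the benchmark generator values."""
    mode = stiefel.sample_uniform(3, 2, rng)
    return model.ModelParams(
        F=vmf.VMFParam(mode * np.array([25.0, 10.0])),
        mu=np.array([20.0, 10.0]),
        sigma_lambda=2.0,
        sigma_eps=0.1,
    )


@pytest.fixture()
def medium_params(rng):
    """An (n=8, p=3) model used by mid-size sampler/likelihood tests."""
    mode = stiefel.sample_uniform(8, 3, rng)
    return model.ModelParams(
        F=vmf.VMFParam(mode * np.array([60.0, 40.0, 25.0])),
        mu=np.array([12.0, 8.0, 5.0]),
        sigma_lambda=1.5,
        sigma_eps=0.3,
    )
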