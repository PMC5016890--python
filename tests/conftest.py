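import numpy as np
import pytest

from glscale.curve import FeatureSample, GLParams


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20160909))


@pytest.fixture
def standard_logistic():
    """Q=B=nu=1, M=0: the plain logistic curve centered at 0."""
    return GLParams(Q=1.0, B=1.0, M=0.0, nu=1.0)


@pytest.fixture
def small_sample():
    return FeatureSample.from_values([1.0, 2.0, 3.0])


def random_params(rng) -> GLParams:
    """Moderate random curve parameters, away from saturation regimes."""
    return GLParams(
        Q=float(np.exp(rng.uniform(np.log(0.2), np.log(5.0)))),
        B=float(np.exp(rng.uniform(np.log(0.2), np.log(3.0)))),
        M=float(rng.uniform(-2.0, 2.0)),
        nu=float(np.exp(rng.uniform(np.log(0.3), np.log(3.0)))),
    )
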