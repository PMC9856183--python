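import numpy as np
import pytest

from hctkit import FourPLParams, NoiseSpec


@pytest.fixture
def ctni_bias() -> FourPLParams:
    """Reference cTnI residual-bias curve used across tests."""
    return FourPLParams(lower=34.145 - 31.816, upper=34.145, inflection=52.155, hill=9.175)


@pytest.fixture
def noiseless() -> NoiseSpec:
    return NoiseSpec(rlu_cv=0.0, conc_cv=0.0, sedimentation_sd=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
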