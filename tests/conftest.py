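import numpy as np
import pytest

from tddc import default_protocol, yeast_truth
from tddc.synthetic import generate


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def truth_noiseless():
    return yeast_truth(noise_sigma=0.0)


@pytest.fixture(scope="session")
def dataset_noiseless(protocol, truth_noiseless):
    return generate(truth_noiseless, protocol)


@pytest.fixture(scope="session")
def dataset_noisy(protocol):
    return generate(yeast_truth(noise_sigma=0.005, seed=7), protocol)
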