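import numpy as np
import pytest

from normsim import make_ground_truth, sample_ages, simulate_sample


@pytest.fixture(scope="session")
def lin_gt():
    return make_ground_truth("LinMean_ConstVar")


@pytest.fixture(scope="session")
def nonlin_gt():
    return make_ground_truth("NonLinMean_NonConstVar")


@pytest.fixture(scope="session")
def design_2000():
    return sample_ages(2000, seed=7)


@pytest.fixture(scope="session")
def nonlin_sample_2000(nonlin_gt, design_2000):
    return simulate_sample(nonlin_gt, design_2000, replicate_index=0, base_seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
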