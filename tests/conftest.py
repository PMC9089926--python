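import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import catperc as cp
from catperc import runner as rn

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def fast_config(**kw) -> rn.RunConfig:
    """A cheap RunConfig for functional tests: small RBM-1, short pretraining."""
    base = dict(h1_size=64, pretrain_epochs=5, epochs=20)
    base.update(kw)
    return rn.RunConfig(**base)


@pytest.fixture(scope="session")
def dataset():
    return cp.generate_dataset()


@pytest.fixture(scope="session")
def retinas(dataset):
    return cp.stimuli.dataset_retinas(dataset)


@pytest.fixture(scope="session")
def labels(dataset):
    return cp.stimuli.dataset_attribute_indices(dataset)


@pytest.fixture(scope="session")
def fast_rbm1(retinas):
    """Briefly pretrained small RBM-1 shared by functional runner tests."""
    return rn.pretrain_for_config(fast_config(), retinas)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
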