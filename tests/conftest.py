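import numpy as np
import pytest

from damgcn import SyntheticSpec, generate_domain_pair, worked_micro_fixture


@pytest.fixture(scope="session")
def micro():
    """Deterministic 6-node instance with hand-checked intermediates."""
    return worked_micro_fixture()


@pytest.fixture(scope="session")
def tiny_pair():
    """Small separable domain pair for fast end-to-end tests."""
    spec = SyntheticSpec(n_source=60, n_target=60, d=8, class_sep=4.0,
                         shift=0.5, imbalance=0.25, k=3, seed=7)
    return generate_domain_pair(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
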