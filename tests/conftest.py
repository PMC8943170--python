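import numpy as np
import pytest

import edkernel as ek


@pytest.fixture(scope="session")
def worked():
    """The fixed hand-verified micro-fixture (x, x', x0, expected)."""
    return ek.worked_pair()


@pytest.fixture(scope="session")
def small_ds():
    """A small deterministic synthetic dataset shared across module tests."""
    return ek.generate(ek.SyntheticConfig(n_per_class=6, length_law=(10, 30), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_ids(n):
    return tuple(f"i{k}" for k in range(n))


@pytest.fixture(scope="session")
def separable_kernel():
    """Block-diagonal two-class kernel that is trivially separable."""
    y = np.array([1] * 6 + [-1] * 6)
    K = np.outer(y, y).astype(float) + np.eye(12)
    return ek.KernelMatrix(K, make_ids(12)), y
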