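import numpy as np
import pytest
from hypothesis import settings

from cbal import Pool, PoolSpec, make_feature_pool
from cbal.balancer import AnnotationOracle

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_pool():
    """2,000-sample pool at 5% minority, moderately separable."""
    return make_feature_pool(PoolSpec(n_total=2000, minority_fraction=0.05, class_separation=2.0, dim=5, seed=42))


@pytest.fixture()
def oracle(small_pool):
    return AnnotationOracle.from_pool(small_pool)


@pytest.fixture()
def tiny_pool():
    """Hand-built 6-sample pool: 2 minority, 4 majority, separable."""
    X = np.array([[5.0, 5.0], [6.0, 5.0], [0.0, 0.0], [0.5, 0.0], [0.0, 0.5], [1.0, 1.0]])
    y = np.array([1, 1, 0, 0, 0, 0])
    ids = np.array([f"t{i}" for i in range(6)], dtype=object)
    return Pool(ids=ids, X=X, y=y)
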