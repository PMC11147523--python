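import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """A small, clearly separable two-class feature table."""
    from ggwokelm.synthetic_data import make_classification_data

    return make_classification_data(
        n=80, k_informative=3, k_noise=2, class_sep=5.0, seed=1
    )


@pytest.fixture(scope="session")
def rings_data():
    """Concentric rings: radially separable, not linearly separable."""
    rng = np.random.default_rng(0)
    n = 120
    radii = np.concatenate(
        [rng.normal(1.0, 0.15, n // 2), rng.normal(3.0, 0.15, n // 2)]
    )
    theta = rng.uniform(0, 2 * np.pi, n)
    x = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return x, y
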