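import numpy as np
import pytest

from unsupfe import ExpressionMatrix, gaussian_with_outliers


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mixture():
    """Canonical calibration scenario: 1000 standard-normal values + 100 at 5."""
    return gaussian_with_outliers(seed=11)


@pytest.fixture
def small_matrix(rng):
    values = rng.poisson(50, size=(30, 6)).astype(float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(30)],
        [f"s{j}" for j in range(6)],
    )
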