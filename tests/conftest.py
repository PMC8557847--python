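import numpy as np
import pytest

from sdcornet.dataio import ExpressionMatrix, generate_synthetic_expression


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """6 genes x 5 samples with a mix of correlated and flat-ish rows."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 4.0, 6.0, 8.0, 10.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [1.0, 4.0, 9.0, 16.0, 25.0],
            [3.1, 0.2, 7.5, 2.2, 4.9],
            [0.5, 6.3, 1.8, 9.1, 2.7],
        ]
    )
    return ExpressionMatrix(values, [f"g{i}" for i in range(6)], [f"s{j}" for j in range(5)])


@pytest.fixture(scope="session")
def module_data():
    """Default two-module synthetic dataset with ground truth (seed fixed)."""
    return generate_synthetic_expression(seed=11)


@pytest.fixture(scope="session")
def true_pair_set(module_data):
    _, truth = module_data
    return {tuple(p) for p in truth.true_pairs}
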