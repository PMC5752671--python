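import numpy as np
import pytest

import mergeprior as mp


@pytest.fixture
def tiny_expression():
    # 2 genes x 3 samples, values 1..6
    return mp.ExpressionMatrix(
        ["g1", "g2"], ["s1", "s2", "s3"], np.arange(1.0, 7.0).reshape(2, 3)
    )


@pytest.fixture
def toy_pair_data():
    """10 genes x 3 drugs x 8 samples with one planted strong association."""
    rng = np.random.default_rng(42)
    X = mp.ExpressionMatrix(
        [f"g{i}" for i in range(10)],
        [f"s{j}" for j in range(8)],
        rng.standard_normal((10, 8)),
    )
    y = X.values[0] * 0.9 + 0.1 * rng.standard_normal(8)
    Y = mp.DrugResponseMatrix(
        ["dA", "dB", "dC"],
        X.sample_ids,
        np.vstack([y, rng.standard_normal((2, 8))]),
    )
    return X, Y


@pytest.fixture(scope="session")
def synthetic_screen():
    """Moderate synthetic screen shared across model/evaluation tests."""
    X, Y, D, classes, truth = mp.generate_dataset(p=300, q=20, n=30, seed=11)
    return X, Y, D, classes, truth


@pytest.fixture(scope="session")
def fitted_results(synthetic_screen):
    X, Y, D, classes, truth = synthetic_screen
    assoc = mp.pairwise_association(X, Y)
    results = mp.fit_merge(assoc, D)
    return assoc, results
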