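import numpy as np
import pytest

from fdnn import ExpressionDataset, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def separable_dataset():
    """One informative feature separates the classes; 49 noise features."""
    rng = np.random.default_rng(42)
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 50))
    X[:, 7] = np.where(y == 1, 1.0, -1.0) * 2 + rng.standard_normal(n) * 0.1
    return ExpressionDataset(X=X, y=y)


@pytest.fixture(scope="session")
def small_clustered():
    """A small clustered-case synthetic dataset plus its ground truth."""
    cfg = SimulationConfig(p=300, n=150, p0=20, num_cores=2, case="clustered")
    dataset, outcome, network = generate_dataset(cfg, seed=11)
    return dataset, outcome, network
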