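import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gsompul.similarity import DrugFeatureMatrix
from gsompul.synthetic_data import BenchmarkConfig, generate_benchmark


@pytest.fixture(scope="session")
def two_source_matrices():
    """Two tiny sources with hand-set binary rows (3 drugs)."""
    m1 = DrugFeatureMatrix(
        source_name="chem",
        drug_ids=("A", "B", "C"),
        feature_ids=("f1", "f2", "f3"),
        values=np.array([[1, 1, 0], [1, 0, 1], [0, 0, 0]]),
    )
    m2 = DrugFeatureMatrix(
        source_name="target",
        drug_ids=("A", "B", "C"),
        feature_ids=("g1", "g2"),
        values=np.array([[1, 0], [1, 0], [0, 1]]),
    )
    return [m1, m2]


@pytest.fixture(scope="session")
def gaussian_mixture():
    """Four well-separated 2-D clusters, 200 points, fixed seed."""
    rng = np.random.default_rng(42)
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    X = np.vstack([c + rng.normal(0, 0.5, size=(50, 2)) for c in centers])
    labels = np.repeat(np.arange(4), 50)
    return X, labels


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale benchmark shared by profiling/classification tests."""
    cfg = BenchmarkConfig(n_drugs=60, seed=11)
    matrices, truth = generate_benchmark(cfg)
    return cfg, matrices, truth
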