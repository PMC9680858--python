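import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import coexnet as cx

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_expression():
    """500-gene atlas with one 20-gene module (noise_sd 0.5, 24 samples)."""
    return cx.simulate_expression(n_genes=500, n_samples=24,
                                  module_sizes={"M1": 20}, noise_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def planted_scores(planted_expression):
    m, _ = planted_expression
    c = cx.correlation_matrix(m)
    return c, cx.coexpression_scores(c)


@pytest.fixture(scope="session")
def demo():
    return cx.oil_body_demo(seed=7)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{j}" for j in range(12)]
    vals = rng.normal(5.0, 2.0, size=(30, 12))
    return cx.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), scale="log2")


@pytest.fixture()
def toy_samples():
    return pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(12)],
        "group": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
        "study": "toy",
        "qc_value": 1.0,
    })
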