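import numpy as np
import pytest

from comre import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 30 samples of Gaussian log2-like expression."""
    values = 8.0 + rng.standard_normal((10, 30))
    genes = [f"G{i:02d}" for i in range(10)]
    samples = [f"S{k:02d}" for k in range(30)]
    return ExpressionMatrix(genes, samples, values)


def make_matrix(values, gene_prefix="G", sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i:03d}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{k:03d}" for k in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)
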