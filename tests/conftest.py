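import numpy as np
import pandas as pd
import pytest

from coexwire.data_io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values: np.ndarray, cohorts: dict[str, str] | None = None,
                gene_prefix: str = "G", sample_prefix: str = "S") -> ExpressionMatrix:
    g, n = values.shape
    genes = [f"{gene_prefix}{i + 1:03d}" for i in range(g)]
    samples = [f"{sample_prefix}{j + 1:03d}" for j in range(n)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        cohorts or {},
        scale_note="test",
        log_base=2.0,
    )


@pytest.fixture
def random_matrix(rng):
    """20 genes x 30 samples of i.i.d. noise."""
    return make_matrix(rng.standard_normal((20, 30)))
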