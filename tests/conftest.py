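import numpy as np
import pandas as pd
import pytest

from scgrn.io import CLASS_A, CLASS_B, ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes × 2 cells with exact values."""
    df = pd.DataFrame(
        [[1.0, 2.0], [0.0, 3.0], [4.5, 0.5]],
        index=["g1", "g2", "g3"], columns=["c1", "c2"],
    )
    return ExpressionMatrix(df)


def make_labelled(values: np.ndarray, n_a: int, n_b: int,
                  gene_prefix: str = "g") -> ExpressionMatrix:
    """Wrap an array into a labelled matrix: first n_a cells class_a."""
    n_genes = values.shape[0]
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    cells = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    labels = pd.Series([CLASS_A] * n_a + [CLASS_B] * n_b, index=cells)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells),
                            labels=labels, log_transformed=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
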