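import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from bregtools.containers import CountsMatrix, ExpressionMatrix
from bregtools.simulate import SimConfig


def make_counts(arr, barcodes=None, genes=None) -> CountsMatrix:
    arr = np.asarray(arr)
    n, g = arr.shape
    barcodes = barcodes or [f"cell{i:03d}" for i in range(n)]
    genes = genes or [f"g{j:03d}" for j in range(g)]
    return CountsMatrix(sparse.csr_matrix(arr), barcodes, genes)


def make_expr(arr, barcodes=None, genes=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    n, g = arr.shape
    barcodes = barcodes or [f"cell{i:03d}" for i in range(n)]
    genes = genes or [f"g{j:03d}" for j in range(g)]
    return ExpressionMatrix(arr, barcodes, genes)


@pytest.fixture
def small_config() -> SimConfig:
    """A fast 5-organ config sized so most cells pass QC."""
    return SimConfig(
        seed=11,
        cells_per_organ=150,
        n_genes=500,
        n_signature_genes=60,
        n_b10_signature_genes=20,
        library_size_mean=1200.0,
        expanded_clone_size=8,
        shared_clone_pairs=(("liver", "PC", 3), ("spleen", "PC", 3)),
    )
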