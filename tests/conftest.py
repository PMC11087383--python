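import numpy as np
import pytest
import scipy.sparse as sp

from tcrscreen.matrix import CountMatrix
from tcrscreen.qc import log_normalize


def make_counts(array, genes=None, barcodes=None) -> CountMatrix:
    """CountMatrix from a dense (genes x cells) array with default names."""
    a = np.asarray(array)
    genes = genes or [f"G{i}" for i in range(a.shape[0])]
    barcodes = barcodes or [f"BC{j}" for j in range(a.shape[1])]
    return CountMatrix(genes=list(genes), barcodes=list(barcodes), counts=sp.csr_matrix(a))


def random_norm_matrix(rng, n_genes=None, n_cells=None):
    """A random log-normalized matrix for scoring property tests."""
    n_genes = n_genes or int(rng.integers(5, 51))
    n_cells = n_cells or int(rng.integers(2, 31))
    counts = rng.poisson(rng.uniform(0.2, 5.0), size=(n_genes, n_cells))
    # ensure no zero-total cell
    counts[0, counts.sum(axis=0) == 0] = 1
    return log_normalize(make_counts(counts))


@pytest.fixture
def toy_counts():
    """4-gene, 3-cell toy with mitochondrial and CD3 genes."""
    genes = ["MT-CO1", "CD3D", "CD3E", "ACTB"]
    #                  cell0  cell1  cell2
    data = np.array([[2, 0, 0],   # MT-CO1
                     [1, 0, 3],   # CD3D
                     [0, 0, 1],   # CD3E
                     [7, 0, 4]])  # ACTB
    return make_counts(data, genes=genes, barcodes=["c0", "c1", "c2"])
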