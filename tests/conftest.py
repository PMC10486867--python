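import numpy as np
import pytest
import scipy.sparse as sp

from scgem.datamodel import CountMatrix, build_tree_spec
from scgem.simulate import PlantedTreeParams, simulate_planted_tree


def make_counts(arr, genes=None, barcodes=None):
    arr = np.asarray(arr)
    genes = genes or [f"G{j}" for j in range(arr.shape[1])]
    barcodes = barcodes or [f"C{i}" for i in range(arr.shape[0])]
    return CountMatrix(sp.csr_matrix(arr), genes, barcodes)


@pytest.fixture(scope="session")
def small_tree():
    return build_tree_spec([2, 2])


@pytest.fixture(scope="session")
def planted_corpus():
    """A small planted-tree corpus with ground truth, shared across tests."""
    spec = build_tree_spec([3, 2, 2])
    counts, theta_true, beta_true = simulate_planted_tree(
        PlantedTreeParams(spec=spec, n_cells=800, n_genes=900,
                          parent_share=0.3, seed=42))
    return spec, counts, theta_true, beta_true
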