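import numpy as np
import pytest
import scipy.sparse as sp

from dropcount.io_formats import BarcodeWhitelist, GeneBarcodeMatrix


@pytest.fixture
def small_whitelist() -> BarcodeWhitelist:
    return BarcodeWhitelist(
        sequences=["AAAACCCCGGGGTT", "AAAACCCCGGGGTG", "CCCCGGGGTTTTAA"],
        prior_counts={"AAAACCCCGGGGTT": 900, "AAAACCCCGGGGTG": 100},
    )


def make_matrix(counts, genes=None, barcodes=None) -> GeneBarcodeMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if genes is None:
        genes = [f"G{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"BC{j}" for j in range(n_cells)]
    return GeneBarcodeMatrix(
        genes=list(genes), barcodes=list(barcodes), counts=sp.csr_matrix(counts)
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
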