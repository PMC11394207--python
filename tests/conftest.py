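import numpy as np
import pytest

from panethkit import PipelineConfig
from panethkit.core import CountMatrix


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_count_matrix(rng, n_cells, n_genes, n_mito=3, max_count=20):
    """Small random raw count matrix with a mito gene block."""
    genes = [f"mt-{i}" for i in range(n_mito)] \
        + [f"g{i}" for i in range(n_genes - n_mito)]
    cells = [f"c{i}" for i in range(n_cells)]
    counts = rng.integers(0, max_count, size=(n_cells, n_genes))
    # sparsify
    counts[rng.random((n_cells, n_genes)) < 0.5] = 0
    return CountMatrix(counts, cells, genes, "raw_counts")


def qc_oracle(m, cfg, mito_prefix="mt-"):
    """Brute-force triple-scan QC oracle, independent of the implementation.

    Plain Python loops: (1) drop genes detected in < min_cells cells,
    (2) drop cells with out-of-bounds feature counts, (3) drop cells over
    the mito fraction cut-off.
    """
    X = m.to_dense()
    n_cells, n_genes = X.shape
    keep_genes = []
    for g in range(n_genes):
        detected = sum(1 for i in range(n_cells) if X[i, g] > 0)
        if detected >= cfg.sc_min_cells:
            keep_genes.append(g)
    keep_cells = []
    for i in range(n_cells):
        n_feat = sum(1 for g in keep_genes if X[i, g] > 0)
        if n_feat < cfg.sc_min_features or n_feat > cfg.sc_max_features:
            continue
        total = sum(X[i, g] for g in keep_genes)
        mito = sum(X[i, g] for g in keep_genes
                   if m.col_ids[g].startswith(mito_prefix))
        if total > 0 and mito / total > cfg.sc_max_mito_fraction:
            continue
        keep_cells.append(i)
    cells = [m.row_ids[i] for i in keep_cells]
    genes = [m.col_ids[g] for g in keep_genes]
    return cells, genes, X[np.ix_(keep_cells, keep_genes)]
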