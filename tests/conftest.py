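import numpy as np
import pytest

from sencaf.io import LOGNORM, RAW, CountMatrix


def lognorm_matrix(values, gene_ids=None, barcodes=None, sample_of=None):
    """Wrap a dense array as a lognorm-layer CountMatrix for scoring tests."""
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_g)]
    barcodes = barcodes or [f"c{j+1}" for j in range(n_c)]
    return CountMatrix(values, gene_ids, barcodes, sample_of or {}, LOGNORM)


def raw_matrix(values, gene_ids=None, barcodes=None, sample_of=None):
    values = np.asarray(values)
    n_g, n_c = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_g)]
    barcodes = barcodes or [f"c{j+1}" for j in range(n_c)]
    return CountMatrix(values, gene_ids, barcodes, sample_of or {}, RAW)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated dataset shared across tests that only read it."""
    from sencaf.simulate import SimConfig, simulate_counts

    cfg = SimConfig(n_samples=4, cells_per_sample=(50, 70), n_genes=500, seed=42)
    return simulate_counts(cfg)
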