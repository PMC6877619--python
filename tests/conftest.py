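import numpy as np
import pytest

from hicarch import ContactMatrix, GenomeModel


@pytest.fixture
def genome_one():
    """Single 8-bin chromosome, 25-kb bins."""
    return GenomeModel([("A", 200_000, 2)], 25_000)


@pytest.fixture
def genome_two():
    return GenomeModel([("A", 200_000, 2), ("B", 150_000, 2)], 25_000)


def dense_to_matrix(genome, chrom, dense, kind="balanced"):
    """Build a ContactMatrix from one chromosome's dense symmetric block."""
    lo, _ = genome.bin_range(chrom)
    n = dense.shape[0]
    iu, ju = np.triu_indices(n)
    v = np.asarray(dense, dtype=float)[iu, ju]
    nz = v != 0
    return ContactMatrix(genome, iu[nz] + lo, ju[nz] + lo, v[nz], kind=kind)


def random_cis_block(rng, n=8, lo=50, hi=200, ignore_diags=2):
    """Random symmetric integer block with the first diagonals zeroed."""
    w = rng.integers(lo, hi + 1, size=(n, n)).astype(float)
    w = np.triu(w)
    w = w + w.T - np.diag(np.diag(w))
    for d in range(ignore_diags):
        idx = np.arange(n - d)
        w[idx, idx + d] = 0
        w[idx + d, idx] = 0
    return w
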