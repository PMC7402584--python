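import numpy as np
import pytest

from hicplaid import hic_core as hc
from hicplaid import synthdata as sd


@pytest.fixture
def small_genome():
    """1 chromosome, 10 Mb at 100 kb (100 bins), alternating compartments."""
    return sd.generate_genome(
        n_chrom=1,
        chrom_length=10_000_000,
        bin_size=100_000,
        mean_tad_size=1_000_000,
        compartment_block_bins=10,
        seed=7,
    )


def make_tad_genome(n_tads: int = 10, tad_bins: int = 10, bin_size: int = 40_000):
    """Genome with exactly ``n_tads`` equal TADs of ``tad_bins`` bins each."""
    n = n_tads * tad_bins
    length = n * bin_size
    return sd.SyntheticGenome(
        chromosomes=[("chr1", length)],
        bin_size=bin_size,
        compartment_truth=np.array(["A"] * n, dtype=object),
        tad_truth={
            "chr1": [
                (i * tad_bins * bin_size, (i + 1) * tad_bins * bin_size)
                for i in range(n_tads)
            ]
        },
        bias_truth=np.ones(n),
        seed=0,
    )


@pytest.fixture
def tad_genome():
    return make_tad_genome()


def random_symmetric_counts(n: int, rng: np.random.Generator, lam: float = 20.0):
    """Dense random symmetric count matrix with strictly positive marginals."""
    upper = np.triu(rng.poisson(lam, size=(n, n)) + 1)
    return upper + upper.T - np.diag(np.diag(upper))


def matrix_from_dense(dense: np.ndarray, bin_size: int = 1000, chrom: str = "chr1"):
    n = dense.shape[0]
    bins = hc.BinTable.fixed({chrom: n * bin_size}, bin_size)
    return hc.ContactMatrix(bins=bins, values=dense)
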