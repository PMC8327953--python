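import numpy as np
import pytest

from hapscan import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def matrix_from_strings(haps, chrom="1", positions=None):
    """Build a HaplotypeMatrix from strings like '00101'."""
    alleles = np.array([[int(c) for c in h] for h in haps], dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1)
    return HaplotypeMatrix(chrom=chrom, positions=positions, alleles=alleles)


@pytest.fixture
def toy_pair():
    """The worked two-population example: score at site 3 is ln(11)."""
    pop1 = matrix_from_strings(["00100", "00101", "10101"])
    pop2 = matrix_from_strings(["01100", "10110", "00000"])
    return pop1, pop2


def random_haplotype_matrix(rng, n_haps, n_sites, chrom="1"):
    alleles = rng.integers(0, 2, size=(n_haps, n_sites)).astype(np.uint8)
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.arange(1, n_sites + 1) * 10,
        alleles=alleles,
    )
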