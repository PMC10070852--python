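import numpy as np
import pytest

from methylpop import GenotypeCounts, HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230321)


@pytest.fixture
def andean_high_counts():
    """High-altitude Andean genotype counts reconstructed from published
    genotype proportions (0.42, 0.25, 0.33) x n=24."""
    return GenotypeCounts("HA", 10, 6, 8)


@pytest.fixture
def split_matrix():
    """20 haplotypes x 20 sites, every site split 10/10."""
    a = np.zeros((20, 20), dtype=np.int8)
    a[:10, :] = 1
    return HaplotypeMatrix(np.arange(1, 21), a)


def brute_force_pi(hap: HaplotypeMatrix) -> float:
    """All-pairs loop oracle for mean pairwise differences, counting
    only sites where both haplotypes are non-missing."""
    n = hap.n
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = hap.alleles[i], hap.alleles[j]
            ok = (a != -1) & (b != -1)
            total += int(np.sum((a != b) & ok))
    return total / (n * (n - 1) / 2)
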