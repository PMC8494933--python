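import numpy as np
import pytest

from chromarch import ContactMap, GenomicInterval
from chromarch.intervals import GeneModel


def symmetric(entries, n):
    """Dense symmetric matrix from {(i, j): value} entries."""
    m = np.zeros((n, n))
    for (i, j), v in entries.items():
        m[i, j] = v
        m[j, i] = v
    return m


@pytest.fixture
def toy_map3():
    """3-bin map with the worked interaction-score example (scores 6/8/10)."""
    counts = symmetric({(0, 0): 5, (0, 1): 2, (0, 2): 4, (1, 2): 6}, 3)
    return ContactMap("chr1", 10_000, counts)


@pytest.fixture
def toy_map4():
    """4-bin map with the worked TAD-score example (score 0.5 on bins 1-2)."""
    counts = symmetric(
        {(1, 2): 8, (0, 1): 2, (1, 3): 2, (2, 3): 4, (0, 3): 9}, 4
    )
    return ContactMap("chr1", 10_000, counts)


@pytest.fixture
def random_map20():
    rng = np.random.default_rng(42)
    a = rng.random((20, 20)) * 10 + 1
    return ContactMap("chr1", 10_000, (a + a.T) / 2)


@pytest.fixture
def genes():
    return [
        GeneModel("geneA", "chr1", 100_000, 130_000, "+"),
        GeneModel("geneB", "chr1", 400_000, 380_000, "-"),
        GeneModel("geneC", "chr2", 50_000, 90_000, "+"),
    ]


def interval(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)
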