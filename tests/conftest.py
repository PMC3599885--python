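import numpy as np
import pytest

from hicdyn import BinnedGenome, ZScoreMatrix, bin_genome


@pytest.fixture
def toy_genome() -> BinnedGenome:
    """Two chromosomes, 1 Mb bins: 5 + 3 = 8 bins."""
    return bin_genome([("chrA", 5_000_000), ("chrB", 3_000_000)], window=1_000_000)


def make_zscores(genome, cells, condition=""):
    """Build a ZScoreMatrix from {(i, j): z} over observed cells."""
    n = genome.n_bins
    z = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for (i, j), value in cells.items():
        z[i, j] = z[j, i] = value
        mask[i, j] = mask[j, i] = True
    return ZScoreMatrix(genome=genome, z=z, mask=mask, condition=condition)


@pytest.fixture
def make_z():
    return make_zscores
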