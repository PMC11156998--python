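import numpy as np
import pandas as pd
import pytest

from popsig import GenotypeMatrix, PopulationMap


def make_matrix(calls, pos=None, chrom="1", samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples x variants) array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_v = calls.shape
    if pos is None:
        pos = np.arange(1, n_v + 1) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n_s)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
         "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(list(samples), variants, calls)


@pytest.fixture
def trio_matrix():
    """3 samples x 4 variants with one missing call."""
    calls = [
        [0, 1, 2, 1],
        [1, 1, 0, -1],
        [2, 0, 2, 2],
    ]
    return make_matrix(calls)


@pytest.fixture
def trio_pops(trio_matrix):
    return PopulationMap({s: "popA" for s in trio_matrix.samples})
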