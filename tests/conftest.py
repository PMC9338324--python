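import numpy as np
import pytest

from popmix import GenotypeMatrix


def make_gm(raw, missing=None, ids=None):
    """GenotypeMatrix from a nested list of raw allele labels, (N, L, 2)."""
    raw = np.asarray(raw)
    if missing is None:
        missing = np.zeros(raw.shape, dtype=bool)
    n, L, _ = raw.shape
    ids = ids or [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix.from_raw(
        raw, np.asarray(missing), ids, [f"locus{l + 1}" for l in range(L)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gm():
    """Six individuals, three diallelic loci with visible structure."""
    raw = [
        [[0, 0], [0, 0], [0, 1]],
        [[0, 0], [0, 1], [0, 0]],
        [[0, 1], [0, 0], [0, 0]],
        [[1, 1], [1, 1], [0, 1]],
        [[1, 1], [0, 1], [1, 1]],
        [[0, 1], [1, 1], [1, 1]],
    ]
    return make_gm(raw)
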