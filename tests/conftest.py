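import numpy as np
import pytest

from catensemble import CategoricalMatrix


def make_cat(codes, missing=None, labels=None):
    codes = np.asarray(codes, dtype=np.int64)
    if missing is None:
        missing = np.zeros_like(codes, dtype=bool)
    missing = np.asarray(missing, dtype=bool)
    n, j = codes.shape
    if labels is None:
        labels = [f"r{i}" for i in range(n)]
    cards = np.array(
        [len(np.unique(codes[~missing[:, c], c])) for c in range(j)], dtype=np.int64
    )
    return CategoricalMatrix(codes, missing, labels, cards)


def random_cat(rng, n, J, m=4, missing_frac=0.0):
    codes = rng.integers(1, m + 1, size=(n, J))
    missing = rng.random((n, J)) < missing_frac
    # keep every column at least partly observed
    for j in range(J):
        if missing[:, j].all():
            missing[rng.integers(0, n), j] = False
    return make_cat(codes, missing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
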