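import numpy as np
import pytest

from mixedgwas import MISSING, GenotypeMatrix


def random_counts(rng, n, m, maf=(0.1, 0.5), missing_rate=0.0):
    """Random hard-call matrix with optional missingness."""
    p = rng.uniform(*maf, size=m)
    counts = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    if missing_rate:
        counts[rng.random((n, m)) < missing_rate] = MISSING
    return counts


def random_operator(rng, n, m, **kw) -> GenotypeMatrix:
    return GenotypeMatrix(random_counts(rng, n, m, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
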