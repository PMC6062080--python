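import logging
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

# routine per-replicate variant drops are noise at test time
logging.getLogger("towmut").setLevel(logging.ERROR)


def random_instance(rng, n=50, M=4, K=3, maf=0.3):
    """A random centered genotype/trait pair with no monomorphic columns."""
    while True:
        X = rng.binomial(2, maf, size=(n, M)).astype(float)
        if np.all(X.std(axis=0) > 0):
            break
    Y = rng.standard_normal((n, K))
    return X - X.mean(axis=0), Y - Y.mean(axis=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
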