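import numpy as np
import pytest


@pytest.fixture
def worked_example():
    """Balanced six-subject marker with a binary trait: T = 4.0 exactly."""
    G = np.array([0, 0, 1, 1, 2, 2], dtype=float)
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    return G, y


@pytest.fixture
def cc_table():
    """2x3 table (controls, cases) with score statistic 6.6667."""
    return np.array([[20.0, 10.0, 10.0], [10.0, 10.0, 20.0]])


def random_instance(rng, n=None, q=None, ensure_all=True):
    """Random genotype/phenotype data with all three genotype classes."""
    n = n or int(rng.integers(30, 120))
    q = q or int(rng.integers(1, 4))
    while True:
        G = rng.integers(0, 3, size=n)
        if not ensure_all or len(np.unique(G)) == 3:
            break
    Y = rng.normal(size=(n, q))
    return G.astype(float), Y
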