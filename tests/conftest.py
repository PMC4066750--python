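import numpy as np
import pytest

from nbrobust.core import CountMatrix, make_group_design


@pytest.fixture
def rng():
    return np.random.default_rng(20140420)


@pytest.fixture
def small_nb_dataset(rng):
    """50 features x 10 samples, two groups, NB(phi=0.2), no DE."""
    mu = rng.uniform(20, 200, size=(50, 1)) * np.ones((1, 10))
    phi = 0.2
    y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu))
    counts = CountMatrix(y)
    design = make_group_design(["A"] * 5 + ["B"] * 5)
    return counts, design, np.full(50, phi)
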