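import numpy as np
import pytest

from bayesahc import SumOfSquares, load_toy_example


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy():
    """Six-variable HIV summary-table fixture (n = 107, covariance scale)."""
    return load_toy_example()


@pytest.fixture(scope="session")
def toy_corr():
    return load_toy_example(mode="correlation")


def random_pd(rng, d, n_extra=3):
    """Random symmetric positive definite matrix (Gram of a tall Gaussian)."""
    a = rng.standard_normal((d + n_extra, d))
    return a.T @ a


def random_sos(rng, d=None, n=None):
    """Sum of squares of a random Gaussian dataset."""
    d = d if d is not None else int(rng.integers(2, 7))
    n = n if n is not None else int(rng.integers(d + 2, 40))
    return SumOfSquares.from_data(rng.standard_normal((n, d)))
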