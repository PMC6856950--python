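import numpy as np
import pytest

from chromstruct import ContactMatrix, simulate_contact_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_curve(rng):
    """A generic non-degenerate test curve, n=30."""
    return rng.standard_normal((30, 3))


@pytest.fixture
def random_contacts(random_curve):
    """Poisson contacts simulated from the random curve."""
    return simulate_contact_matrix(random_curve, a=-3.0, b=50.0, seed=7)


@pytest.fixture
def small_symmetric_counts():
    counts = np.array(
        [
            [0, 2, 1],
            [2, 0, 0],
            [1, 0, 0],
        ],
        dtype=float,
    )
    return ContactMatrix(counts)
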