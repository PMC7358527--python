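import numpy as np
import pytest

from soilvir import GeneratorParams, generate_study

TREATMENTS = ("T1", "T4", "T7", "T8", "SF2")
MONTHS = ("May", "June", "July", "September", "October", "November")


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def study(default_params):
    """One full synthetic study shared across read-only tests."""
    return generate_study(default_params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric dissimilarity matrix with zero diagonal, no ties."""
    upper = rng.uniform(1.0, 100.0, size=n * (n - 1) // 2)
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mat[iu] = upper
    return mat + mat.T
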