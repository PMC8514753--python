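import numpy as np
import pytest

from ilpmda import (
    AssociationMatrix,
    SimilarityKernel,
    SyntheticSpec,
    generate_benchmark,
)


def make_kernel(rng, n, side="disease", labels=None, zero_diag=False):
    """Random symmetric kernel in [0, 1] with unit diagonal."""
    M = rng.uniform(0.0, 1.0, size=(n, n))
    K = (M + M.T) / 2.0
    np.fill_diagonal(K, 0.0 if zero_diag else 1.0)
    if labels is None:
        labels = [f"{side[0]}{i:03d}" for i in range(n)]
    return SimilarityKernel(K, labels, side)


def make_association(rng, nd, nm, density=0.3):
    """Random binary association matrix with at least one positive."""
    A = (rng.uniform(size=(nd, nm)) < density).astype(float)
    A[rng.integers(nd), rng.integers(nm)] = 1.0
    return AssociationMatrix(
        A, [f"d{i:03d}" for i in range(nd)], [f"m{j:03d}" for j in range(nm)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_benchmark():
    """The default synthetic study conditions (60 x 80, rank 4, seed 42)."""
    return generate_benchmark()


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down benchmark for protocol tests that rerun the pipeline."""
    return generate_benchmark(
        SyntheticSpec(nd=15, nm=20, rank=3, density=0.15, seed=7)
    )
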