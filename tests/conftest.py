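import numpy as np
import pytest

from lplni import BlockNetworkSpec, InteractionMatrix, generate_dataset


@pytest.fixture
def tiny_Y():
    """2 drugs x 2 targets identity interactions."""
    return InteractionMatrix(
        values=np.eye(2), drug_ids=["D1", "D2"], target_ids=["T1", "T2"]
    )


@pytest.fixture(scope="session")
def block_fixture():
    """The seeded planted-block network used by the recovery checks."""
    spec = BlockNetworkSpec(
        nd=60, nt=40, n_blocks=3, p_in=0.5, p_out=0.02, seed=7
    )
    Y, X = generate_dataset(spec)
    return spec, Y, X


@pytest.fixture(scope="session")
def small_block_fixture():
    """A smaller planted-block network for the slower full-refit paths."""
    spec = BlockNetworkSpec(
        nd=24, nt=16, n_blocks=2, p_in=0.6, p_out=0.05, seed=3
    )
    Y, X = generate_dataset(spec)
    return spec, Y, X


def make_row_stochastic(rng, nd):
    """Random nonnegative matrix with zero diagonal and unit row sums."""
    W = rng.random((nd, nd))
    np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)
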