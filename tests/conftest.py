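import numpy as np
import pandas as pd
import pytest

from dmbn import PerturbationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20130905)


def random_matrix(rng, n_genes=30, n_mutants=4, density=0.4) -> PerturbationMatrix:
    """Random valid perturbation matrix with the given DEG density."""
    calls = np.where(
        rng.random((n_genes, n_mutants)) < density,
        rng.choice([-1, 1], size=(n_genes, n_mutants)),
        0,
    )
    return PerturbationMatrix(
        pd.DataFrame(
            calls,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"m{j}" for j in range(n_mutants)],
        )
    )


@pytest.fixture
def matrix_factory():
    return random_matrix
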