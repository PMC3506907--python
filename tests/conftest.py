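import numpy as np
import pytest

import grnbench as gb


@pytest.fixture(scope="session")
def small_network():
    """A 30-gene scale-free benchmark network."""
    return gb.generate_source_network(30, tf_fraction=0.2, mean_degree=1.8,
                                      seed=11)


@pytest.fixture(scope="session")
def small_model(small_network):
    return gb.assign_kinetics(small_network, seed=12)


@pytest.fixture(scope="session")
def multifactorial_data(small_model):
    return gb.simulate_experiment(small_model, "multifactorial",
                                  n_samples=80, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(97)


def random_mi_matrix(rng, n=6):
    """A random valid symmetric nonnegative MI-like matrix."""
    a = rng.uniform(0, 1, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0.0)
    genes = [f"g{i}" for i in range(n)]
    return gb.MIMatrix(values=m, gene_ids=genes, estimator="empirical")
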