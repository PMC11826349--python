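import numpy as np
import pytest

from connharm.io import Connectome, default_labels
from connharm.simulate import GeneratorConfig, generate_cohort


def make_connectome(weights) -> Connectome:
    w = np.asarray(weights, dtype=float)
    return Connectome(weights=w, node_labels=default_labels(w.shape[0]))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, quick-to-train two-site cohort with the default effects."""
    config = GeneratorConfig(n_nodes=20, n_per_site=30, seed=7)
    cohort, truth = generate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def tiny_trained(tiny_cohort):
    """A co-learning model trained on the tiny cohort (shared across tests)."""
    from connharm.measures import measures_table
    from connharm.vae import ModelConfig, train

    config, cohort, _ = tiny_cohort
    n = cohort.n_nodes
    table = measures_table(cohort, seed=0)
    mc = ModelConfig(
        input_dim=n * (n - 1) // 2, n_sites=2, hidden_dim=32, latent_dim=8,
        epochs=40, batch_size=16, seed=5,
    )
    return cohort, table, mc, train(cohort, table, mc)


@pytest.fixture
def triangle():
    return make_connectome([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def path3():
    return make_connectome([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def path4():
    return make_connectome(
        [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]]
    )


@pytest.fixture
def star5():
    """Star: center node 0 with 4 leaves."""
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    return make_connectome(w)


@pytest.fixture
def k4():
    w = np.ones((4, 4)) - np.eye(4)
    return make_connectome(w)
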