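import logging

import numpy as np
import pytest

import pcorsel as pc

# the discordant-sign warnings are expected in bulk simulation runs
logging.getLogger("pcorsel").setLevel(logging.ERROR)


@pytest.fixture
def small_model():
    """A p=15 Erdős–Rényi ground-truth model with its realized graph."""
    graph = pc.random_graph(15, "erdos_renyi", 0.15, seed=11)
    return pc.build_precision_model(graph, seed=11)


@pytest.fixture
def small_data(small_model):
    return pc.sample_gaussian(small_model, n=2000, seed=12)


def truth_pcor(model):
    return pc.PartialCorrelationMatrix(values=model.pcor, variable_labels=model.graph.node_labels)


def classical_pcor(data):
    """Independent oracle: invert the sample covariance, apply the
    precision-to-pcor transform."""
    S = np.cov(data.values, rowvar=False)
    omega = np.linalg.inv(S)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho
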