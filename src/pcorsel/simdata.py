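"""Synthetic ground truth for GGM experiments.

The generator follows a five-step recipe: (1) draw a random graph
(Erdős–Rényi for the typically non-decomposable scenarios, Barabási–Albert
preferential attachment for decomposable ones), (2) place uniform random
weights, with random signs, on the upper-triangular adjacency entries,
(3) form the sparse positive-definite precision matrix Ω = (I+W)ᵀ(I+W),
(4) normalize Ω into a partial correlation matrix, and (5) sample from the
zero-mean multivariate Gaussian with covariance Ω⁻¹.

The Gram construction in step 3 introduces fill-in: the realized graph G~
(the nonzero pattern of Ω) is a supergraph of the drawn graph, slightly
different from it, and it is G~ — not the drawn graph — that is the ground
truth attached to the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

from .graph import IndependenceGraph

# off-diagonal precision entries below this magnitude count as structural zeros
FILLIN_TOL = 1e-12


@dataclass(frozen=True)
class PrecisionModel:
    """Sparse SPD precision matrix, its partial correlation matrix, and the realized graph."""

    graph: IndependenceGraph
    pcor: np.ndarray
    precision: np.ndarray
    seed: int


@dataclass(frozen=True)
class Dataset:
    """An n × p data matrix with variable labels."""

    values: np.ndarray
    variable_labels: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 2:
            raise ValueError("values must be an n x p matrix with n >= 2")
        if vals.shape[1] != len(self.variable_labels):
            raise ValueError("column count must equal the number of variable labels")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values contain missing or non-finite entries")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "variable_labels", tuple(self.variable_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _labels(p: int) -> tuple[str, ...]:
    return tuple(f"V{i + 1}" for i in range(p))


def random_graph(p: int, model: str, density_or_attach: float | int, seed: int) -> IndependenceGraph:
    """Draw a random graph on ``p`` nodes labeled V1..Vp.

    Parameters
    ----------
    model : {"erdos_renyi", "barabasi"}
        ``erdos_renyi`` takes an edge probability in (0, 1) (0 and 1 give
        the empty and complete graph); ``barabasi`` takes a preferential
        attachment count m >= 1 (m = 1 yields a tree, hence a chordal graph).
    """
    if not isinstance(p, (int, np.integer)) or p < 2:
        raise ValueError(f"p must be an integer >= 2, got p={p!r}")
    if model == "erdos_renyi":
        density = float(density_or_attach)
        if not 0.0 <= density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got density={density!r}")
        g = nx.gnp_random_graph(p, density, seed=seed)
    elif model == "barabasi":
        attach = int(density_or_attach)
        if attach < 1:
            raise ValueError(f"attach must be >= 1, got attach={density_or_attach!r}")
        g = nx.barabasi_albert_graph(p, attach, seed=seed)
    else:
        raise ValueError(f"unknown graph model {model!r}; expected 'erdos_renyi' or 'barabasi'")
    labels = _labels(p)
    edges = frozenset((labels[a], labels[b]) for a, b in g.edges())
    return IndependenceGraph(labels, edges)


def build_precision_model(
    graph: IndependenceGraph,
    weight_low: float = 0.1,
    weight_high: float = 1.0,
    seed: int = 0,
    random_sign: bool = True,
) -> PrecisionModel:
    """Construct a sparse SPD precision matrix honoring ``graph`` (plus fill-in).

    Upper-triangular weights are drawn uniformly from [weight_low, weight_high]
    (sign randomized to ±1 when ``random_sign``), and Ω = (I+W)ᵀ(I+W). Since
    I+W is unit upper triangular, Ω is symmetric positive definite. The
    realized graph is read off the nonzero pattern of Ω, and the partial
    correlation matrix is ρ_ij = −ω_ij/√(ω_ii ω_jj) with unit diagonal.
    """
    if not weight_low < weight_high:
        raise ValueError(f"weight_low must be < weight_high, got [{weight_low}, {weight_high}]")
    if graph.p < 1:
        raise ValueError("graph must have at least one node")
    rng = np.random.default_rng(seed)
    labels = graph.node_labels
    p = graph.p
    order = {lab: i for i, lab in enumerate(labels)}
    W = np.zeros((p, p))
    # deterministic edge order: upper triangle by (i, j)
    for a, b in sorted(graph.edges, key=lambda e: (order[e[0]], order[e[1]])):
        i, j = order[a], order[b]
        w = rng.uniform(weight_low, weight_high)
        if random_sign and rng.random() < 0.5:
            w = -w
        W[i, j] = w
    omega = (np.eye(p) + W).T @ (np.eye(p) + W)
    omega = (omega + omega.T) / 2.0

    nonzero = np.abs(omega) > FILLIN_TOL
    np.fill_diagonal(nonzero, False)
    realized = IndependenceGraph.from_adjacency(nonzero.astype(int), labels)

    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor[~nonzero] = 0.0
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    return PrecisionModel(graph=realized, pcor=pcor, precision=omega, seed=seed)


def sample_gaussian(model: PrecisionModel, n: int, seed: int) -> Dataset:
    """Draw ``n`` i.i.d. samples from N(0, Ω⁻¹) for the model's precision Ω.

    Sampling goes through the Cholesky factor of Ω: with Ω = LLᵀ and
    Z ~ N(0, I), X = L⁻ᵀZ has covariance (LLᵀ)⁻¹ = Ω⁻¹, avoiding an explicit
    inverse.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got n={n}")
    try:
        L = scipy.linalg.cholesky(model.precision, lower=True)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded by PrecisionModel
        raise ValueError("precision matrix is numerically singular") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((model.precision.shape[0], n))
    X = scipy.linalg.solve_triangular(L, Z, lower=True, trans="T")
    return Dataset(values=X.T, variable_labels=model.graph.node_labels, seed=seed)


def is_decomposable(graph: IndependenceGraph) -> bool:
    """True iff the graph is chordal (every cycle of length >= 4 has a chord)."""
    if graph.p <= 1 or graph.edge_count == 0:
        return True
    return nx.is_chordal(graph.to_networkx())
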