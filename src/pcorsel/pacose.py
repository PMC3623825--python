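"""Graph-constrained partial correlation estimation.

Given a dataset and an independence graph, each variable is regressed on its
graph neighbors only, and the partial correlation for an edge (i, j) is
recovered from the two regression coefficients as

    ρ̂_ij = sign(β̂_ij) · sqrt(β̂_ij · β̂_ji),

while non-edges are written as exact zeros. With the complete graph and OLS
this reduces to the classical unconstrained estimator obtained by inverting
the sample covariance matrix; with a sparse graph the removed covariates
change every regression in which they would have appeared, which is the whole
point of the constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engines import RegressionEngine, analytic_ridge_parameter  # noqa: F401  (re-exported)
from .graph import IndependenceGraph
from .simdata import Dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartialCorrelationMatrix:
    """Symmetric p×p matrix with unit diagonal and entries in [−1, 1]."""

    values: np.ndarray
    variable_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        p = len(self.variable_labels)
        if vals.shape != (p, p):
            raise ValueError("matrix shape does not match number of labels")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "variable_labels", tuple(self.variable_labels))


@dataclass(frozen=True)
class NeighborRegressionFit:
    """Coefficients of one variable regressed on its graph neighbors."""

    response_label: str
    neighbor_labels: tuple[str, ...]
    coefficients: np.ndarray
    engine_used: str
    selected_hyperparameter: float | int | None


def _centered(data: Dataset) -> np.ndarray:
    X = data.values
    return X - X.mean(axis=0)


def _check_labels(data: Dataset, graph: IndependenceGraph) -> IndependenceGraph:
    if set(data.variable_labels) != set(graph.node_labels):
        raise ValueError("data and graph variable sets differ")
    if data.variable_labels != graph.node_labels:
        graph = graph.relabel_order(data.variable_labels)
    return graph


def fit_neighbor_regression(
    data: Dataset, target: str, graph: IndependenceGraph, engine: RegressionEngine
) -> NeighborRegressionFit:
    """Regress ``target`` on its neighbors in ``graph`` (intercept fitted on
    centered data and discarded)."""
    graph = _check_labels(data, graph)
    if target not in data.variable_labels:
        raise KeyError(f"unknown target variable {target!r}")
    X = _centered(data)
    idx = {lab: i for i, lab in enumerate(data.variable_labels)}
    t = idx[target]
    y = X[:, t]
    if np.allclose(y, 0.0):
        raise ValueError(f"response column {target!r} has zero variance")
    nbrs = tuple(graph.neighbors(target))
    if not nbrs:
        return NeighborRegressionFit(target, (), np.zeros(0), engine.name, None)
    cols = [idx[nb] for nb in nbrs]
    coefs, hyper = engine.fit(y, X[:, cols], seed=(engine.seed + t) % (2**31))
    if not np.all(np.isfinite(coefs)):
        raise ValueError(f"engine {engine.name!r} produced non-finite coefficients for {target!r}")
    return NeighborRegressionFit(target, nbrs, np.asarray(coefs, dtype=float), engine.name, hyper)


def pacose(data: Dataset, graph: IndependenceGraph, engine: RegressionEngine) -> PartialCorrelationMatrix:
    """Graph-constrained partial correlation matrix.

    For each edge, ρ̂ is formed from the pair of neighbor-regression
    coefficients; when the two coefficients disagree in sign the square root
    is undefined and the entry is set to 0 (logged), and magnitudes above 1
    (possible with regularized engines) are clipped to ±1 (logged). Non-edges
    are exact zeros by construction.
    """
    graph = _check_labels(data, graph)
    labels = data.variable_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    p = len(labels)

    beta: dict[tuple[str, str], float] = {}
    for lab in labels:
        try:
            fit = fit_neighbor_regression(data, lab, graph, engine)
        except Exception as exc:
            raise RuntimeError(f"regression engine failed for variable {lab!r}: {exc}") from exc
        for nb, c in zip(fit.neighbor_labels, fit.coefficients):
            beta[(lab, nb)] = float(c)

    M = np.eye(p)
    for a, b in graph.edges:
        i, j = idx[a], idx[b]
        bij, bji = beta[(a, b)], beta[(b, a)]
        prod = bij * bji
        if prod > 0.0:
            r = np.sign(bij) * np.sqrt(prod)
            if abs(r) > 1.0:
                logger.warning("clipping |pcor|=%.4f > 1 for pair (%s, %s)", abs(r), a, b)
                r = np.sign(r)
        else:
            if prod < 0.0:
                logger.warning(
                    "discordant regression coefficient signs for pair (%s, %s); setting pcor to 0", a, b
                )
            r = 0.0
        M[i, j] = M[j, i] = r
    return PartialCorrelationMatrix(values=M, variable_labels=labels)


def pcor_to_precision_scale(pcor: PartialCorrelationMatrix, partial_variances: np.ndarray) -> np.ndarray:
    """Rebuild a precision matrix from a pcor matrix and partial variances.

    ``partial_variances[i]`` is the conditional variance of variable i given
    the rest, i.e. 1/ω_ii; the output has Ω_ii = 1/v_i and
    Ω_ij = −ρ_ij √(Ω_ii Ω_jj), preserving the zero pattern.
    """
    v = np.asarray(partial_variances, dtype=float).ravel()
    if v.shape[0] != len(pcor.variable_labels):
        raise ValueError("need one partial variance per variable")
    if np.any(v <= 0):
        raise ValueError("partial variances must be strictly positive")
    d = 1.0 / v
    omega = -pcor.values * np.sqrt(np.outer(d, d))
    np.fill_diagonal(omega, d)
    return omega
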