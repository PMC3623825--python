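"""Reference estimators: precision→pcor transform, shrinkage, IPF covariance selection.

The shrinkage estimator is an unconstrained (graph-ignorant) baseline:
Ledoit–Wolf shrinkage of the correlation matrix toward the identity with the
analytic intensity, inverted and transformed to partial correlations. IPF is
the classical covariance-selection route: cyclic adjustment of the precision
matrix over edge cliques so that the implied covariance matches the sample
covariance on the diagonal and on every edge, while non-edge precision
entries stay exactly zero — converging to the constrained Gaussian MLE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .graph import IndependenceGraph
from .pacose import PartialCorrelationMatrix
from .simdata import Dataset


@dataclass(frozen=True)
class CovarianceEstimate:
    covariance: np.ndarray
    method: str
    precision: np.ndarray | None = None
    converged: bool = True
    sweeps: int = 0


def precision_to_pcor(precision: np.ndarray, variable_labels: tuple[str, ...] | None = None) -> PartialCorrelationMatrix:
    """ρ_ij = −ω_ij/√(ω_ii ω_jj), with unit diagonal."""
    omega = np.asarray(precision, dtype=float)
    p = omega.shape[0]
    if omega.shape != (p, p):
        raise ValueError("precision matrix must be square")
    diag = np.diag(omega)
    if np.any(diag <= 0):
        raise ValueError("precision matrix has a nonpositive diagonal entry")
    d = np.sqrt(diag)
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    labels = tuple(variable_labels) if variable_labels is not None else tuple(f"V{i+1}" for i in range(p))
    return PartialCorrelationMatrix(values=rho, variable_labels=labels)


def shrinkage_pcor(data: Dataset) -> tuple[PartialCorrelationMatrix, float]:
    """Unconstrained shrinkage partial correlations (GeneNet-style baseline).

    Columns are standardized so the covariance being shrunk is the
    correlation matrix and the Ledoit–Wolf identity target coincides with the
    identity correlation matrix; the shrunk matrix is always invertible.
    Returns (pcor, shrinkage intensity in [0, 1]).
    """
    if data.n < 3:
        raise ValueError("shrinkage estimator requires n >= 3")
    X = data.values
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("shrinkage estimator requires non-constant columns")
    Z = (X - X.mean(axis=0)) / sd
    lw = LedoitWolf(assume_centered=True).fit(Z)
    omega = np.linalg.inv(lw.covariance_)
    return precision_to_pcor(omega, data.variable_labels), float(lw.shrinkage_)


def ipf_covariance_selection(
    sample_cov: np.ndarray,
    graph: IndependenceGraph,
    tol: float = 1e-8,
    max_sweeps: int = 5000,
) -> CovarianceEstimate:
    """Constrained Gaussian MLE by iterative proportional fitting over edges.

    Starting from the diagonal precision diag(1/s_ii), each sweep updates the
    2×2 precision block of every edge (and each 1×1 diagonal block) by

        K_aa += S_aa⁻¹ − (Σ_aa)⁻¹,   Σ = K⁻¹,

    which matches the implied covariance to the sample covariance on that
    clique and leaves all other zeros of K untouched. Stops when the largest
    block update in a sweep falls below ``tol``; flags (rather than raises)
    non-convergence after ``max_sweeps``.
    """
    S = np.asarray(sample_cov, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("sample covariance must be square and symmetric")
    if p != graph.p:
        raise ValueError("sample covariance size does not match graph")
    if tol <= 0:
        raise ValueError("tol must be positive")
    order = {lab: i for i, lab in enumerate(graph.node_labels)}
    cliques: list[list[int]] = [[i] for i in range(p)]
    cliques += [sorted((order[a], order[b])) for a, b in graph.edges]
    for a in cliques:
        block = S[np.ix_(a, a)]
        if np.any(np.linalg.eigvalsh(block) <= 0):
            raise ValueError("sample covariance is not positive definite on a clique submatrix")

    if graph.edge_count == p * (p - 1) // 2:
        # no constraints: the MLE is the sample covariance itself
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("sample covariance must be positive definite for the complete graph")
        return CovarianceEstimate(S.copy(), "ipf", np.linalg.inv(S), True, 0)

    K = np.diag(1.0 / np.diag(S))
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        delta = 0.0
        for a in cliques:
            sigma_aa = np.linalg.inv(K)[np.ix_(a, a)]
            update = np.linalg.inv(S[np.ix_(a, a)]) - np.linalg.inv(sigma_aa)
            K[np.ix_(a, a)] += update
            delta = max(delta, float(np.max(np.abs(update))))
        if delta < tol:
            converged = True
            break
    # non-edge entries are exact zeros by construction; enforce against drift
    mask = graph.adjacency().astype(bool)
    np.fill_diagonal(mask, True)
    K[~mask] = 0.0
    K = (K + K.T) / 2.0
    return CovarianceEstimate(np.linalg.inv(K), "ipf", K, converged, sweeps)
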