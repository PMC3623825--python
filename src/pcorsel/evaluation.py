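"""Scoring and stability statistics for GGM inference.

MSE compares estimated and true partial correlation matrices over unordered
variable pairs; PPV and sensitivity compare an estimated graph's edge set
with the truth; Fleiss' κ measures chance-corrected agreement between the
networks inferred from perturbed versions of one dataset (the 10-group
exclusion protocol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .graph import IndependenceGraph
from .pacose import PartialCorrelationMatrix
from .simdata import Dataset


@dataclass(frozen=True)
class GraphConfusion:
    """Edge-level confusion counts over unordered pairs i < j."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class StabilityResult:
    kappa: float
    networks: tuple[IndependenceGraph, ...]
    group_count: int


def pcor_mse(estimate: PartialCorrelationMatrix, truth: PartialCorrelationMatrix) -> float:
    """Mean squared difference over the p(p−1)/2 upper-triangle pairs.

    The diagonal is excluded (identically 1 on both sides), which makes the
    statistic scale-free in p.
    """
    if estimate.variable_labels != truth.variable_labels:
        raise ValueError("estimate and truth must share labels and order")
    iu = np.triu_indices(len(estimate.variable_labels), k=1)
    diff = estimate.values[iu] - truth.values[iu]
    return float(np.mean(diff**2))


def graph_confusion(estimated: IndependenceGraph, truth: IndependenceGraph) -> GraphConfusion:
    if set(estimated.node_labels) != set(truth.node_labels):
        raise ValueError("estimated and true graphs must share the same node set")
    est = estimated.relabel_order(truth.node_labels)
    p = truth.p
    e_est, e_true = est.edges, truth.edges
    tp = len(e_est & e_true)
    fp = len(e_est - e_true)
    fn = len(e_true - e_est)
    tn = p * (p - 1) // 2 - tp - fp - fn
    return GraphConfusion(tp, fp, fn, tn)


def ppv_sensitivity(c: GraphConfusion) -> tuple[float | None, float | None]:
    """PPV = TP/(TP+FP), sensitivity = TP/(TP+FN); 0/0 is reported as None,
    never silently coerced to 0 or 1."""
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return ppv, sens


def _edge_count_table(networks: Sequence[IndependenceGraph]) -> np.ndarray:
    labels = networks[0].node_labels
    p = len(labels)
    pairs = [(labels[i], labels[j]) for i in range(p) for j in range(i + 1, p)]
    counts = np.zeros((len(pairs), 2), dtype=float)
    for g in networks:
        gg = g.relabel_order(labels)
        for k, pair in enumerate(pairs):
            if pair in gg.edges:
                counts[k, 1] += 1
            else:
                counts[k, 0] += 1
    return counts


def fleiss_kappa(networks: Sequence[IndependenceGraph]) -> float:
    """Fleiss' κ with items = unordered node pairs, raters = networks,
    categories = {edge, non-edge}.

    κ = (P̄ − P̄_e)/(1 − P̄_e) ≤ 1. When every network assigns every pair to
    the same single category (P̄_e = 1), agreement is perfect and κ = 1 by
    convention.
    """
    if len(networks) < 2:
        raise ValueError("Fleiss' kappa requires at least 2 networks")
    base = set(networks[0].node_labels)
    if any(set(g.node_labels) != base for g in networks):
        raise ValueError("all networks must share the same node set")
    table = _edge_count_table(networks)
    n_raters = len(networks)
    p_cat = table.sum(axis=0) / (table.shape[0] * n_raters)
    if np.max(p_cat) >= 1.0:
        return 1.0
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def partition_groups(n: int, groups: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous near-equal blocks (remainder spread
    one per leading group)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, groups)
    sizes = [base + (1 if g < rem else 0) for g in range(groups)]
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start : start + s]))
        start += s
    return out


def stability_protocol(
    data: Dataset,
    infer: Callable[[Dataset], IndependenceGraph],
    groups: int = 10,
    seed: int = 0,
) -> StabilityResult:
    """Leave-one-group-out stability: split samples into ``groups`` parts,
    infer a network on each complement, and measure agreement with Fleiss' κ."""
    if groups < 2:
        raise ValueError("groups must be >= 2")
    if data.n < 2 * groups:
        raise ValueError("need at least 2 samples per group")
    parts = partition_groups(data.n, groups, seed)
    networks = []
    for g, held_out in enumerate(parts):
        keep = np.setdiff1d(np.arange(data.n), held_out)
        subset = Dataset(values=data.values[keep], variable_labels=data.variable_labels, seed=data.seed)
        try:
            networks.append(infer(subset))
        except Exception as exc:
            raise RuntimeError(f"inference failed on the subset excluding group {g}: {exc}") from exc
    return StabilityResult(kappa=fleiss_kappa(networks), networks=tuple(networks), group_count=groups)
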