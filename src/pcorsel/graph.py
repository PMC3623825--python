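"""Undirected independence graphs for Gaussian graphical models.

An independence graph encodes, for each unordered pair of variables, whether
the partial correlation between them may be nonzero (edge present) or is
constrained to be exactly zero (edge absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class IndependenceGraph:
    """Undirected graph on labeled nodes; missing edges mean zero partial correlation.

    Parameters
    ----------
    node_labels : tuple of str
        Ordered, distinct variable names.
    edges : frozenset of (str, str)
        Unordered pairs, stored canonically with the endpoint that comes first
        in ``node_labels`` first. No self-loops.
    """

    node_labels: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        labels = tuple(self.node_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("node_labels must be distinct")
        order = {lab: i for i, lab in enumerate(labels)}
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            if a not in order or b not in order:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            canon.add((a, b) if order[a] < order[b] else (b, a))
        object.__setattr__(self, "node_labels", labels)
        object.__setattr__(self, "edges", frozenset(canon))

    # -- constructors -------------------------------------------------------
    @classmethod
    def empty(cls, node_labels: Iterable[str]) -> "IndependenceGraph":
        return cls(tuple(node_labels), frozenset())

    @classmethod
    def complete(cls, node_labels: Iterable[str]) -> "IndependenceGraph":
        labels = tuple(node_labels)
        edges = {(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))}
        return cls(labels, frozenset(edges))

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray, node_labels: Iterable[str]) -> "IndependenceGraph":
        labels = tuple(node_labels)
        A = np.asarray(adjacency)
        if A.shape != (len(labels), len(labels)):
            raise ValueError("adjacency shape does not match number of labels")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency matrix must be symmetric")
        idx = np.argwhere(np.triu(A, k=1) != 0)
        edges = {(labels[i], labels[j]) for i, j in idx}
        return cls(labels, frozenset(edges))

    @classmethod
    def from_networkx(cls, g: nx.Graph, node_labels: Iterable[str] | None = None) -> "IndependenceGraph":
        labels = tuple(node_labels) if node_labels is not None else tuple(str(v) for v in g.nodes())
        return cls(labels, frozenset((str(a), str(b)) for a, b in g.edges()))

    # -- views --------------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def neighbors(self, label: str) -> list[str]:
        """Neighbors of ``label``, in node-label order."""
        if label not in self.node_labels:
            raise KeyError(f"unknown node {label!r}")
        nb = {b if a == label else a for a, b in self.edges if label in (a, b)}
        return [lab for lab in self.node_labels if lab in nb]

    def adjacency(self) -> np.ndarray:
        order = {lab: i for i, lab in enumerate(self.node_labels)}
        A = np.zeros((self.p, self.p), dtype=int)
        for a, b in self.edges:
            A[order[a], order[b]] = A[order[b], order[a]] = 1
        return A

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges)
        return g

    def relabel_order(self, node_labels: Iterable[str]) -> "IndependenceGraph":
        """Same graph with nodes reordered to ``node_labels`` (a permutation)."""
        labels = tuple(node_labels)
        if set(labels) != set(self.node_labels):
            raise ValueError("node sets differ")
        return IndependenceGraph(labels, self.edges)
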