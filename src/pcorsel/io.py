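"""Tab-separated input/output for datasets, graphs and matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .graph import IndependenceGraph
from .pacose import PartialCorrelationMatrix
from .simdata import Dataset


def read_data_tsv(path: str | Path, seed: int = 0) -> Dataset:
    df = pd.read_csv(path, sep="\t")
    return Dataset(values=df.to_numpy(dtype=float), variable_labels=tuple(df.columns), seed=seed)


def write_data_tsv(data: Dataset, path: str | Path) -> None:
    pd.DataFrame(data.values, columns=list(data.variable_labels)).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(values: np.ndarray, labels: tuple[str, ...], path: str | Path) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ; not a labeled square matrix")
    return df.to_numpy(dtype=float), tuple(df.columns)


def read_pcor_tsv(path: str | Path) -> PartialCorrelationMatrix:
    values, labels = read_matrix_tsv(path)
    return PartialCorrelationMatrix(values=values, variable_labels=labels)


def write_pcor_tsv(pcor: PartialCorrelationMatrix, path: str | Path) -> None:
    write_matrix_tsv(pcor.values, pcor.variable_labels, path)


def write_graph_edgelist(graph: IndependenceGraph, path: str | Path) -> None:
    rows = sorted(graph.edges, key=lambda e: ({l: i for i, l in enumerate(graph.node_labels)}[e[0]],
                                              {l: i for i, l in enumerate(graph.node_labels)}[e[1]]))
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


def write_graph_adjacency(graph: IndependenceGraph, path: str | Path) -> None:
    write_matrix_tsv(graph.adjacency(), graph.node_labels, path)


def read_graph(path: str | Path, node_labels: tuple[str, ...] | None = None) -> IndependenceGraph:
    """Read a graph from a two-column edge list or a labeled 0/1 adjacency TSV.

    The format is auto-detected: an edge list has exactly the columns
    ``source`` and ``target``; anything square with matching row/column labels
    is treated as an adjacency matrix. For edge lists, ``node_labels`` supplies
    the full node set (isolated nodes cannot be recovered from edges alone);
    when omitted, the nodes appearing in edges are used in first-seen order.
    """
    df = pd.read_csv(path, sep="\t", index_col=None)
    if list(df.columns) == ["source", "target"]:
        edges = [(str(a), str(b)) for a, b in df.itertuples(index=False)]
        if node_labels is None:
            seen: dict[str, None] = {}
            for a, b in edges:
                seen.setdefault(a)
                seen.setdefault(b)
            node_labels = tuple(seen)
        return IndependenceGraph(tuple(node_labels), frozenset(edges))
    values, labels = read_matrix_tsv(path)
    return IndependenceGraph.from_adjacency((values != 0).astype(int), labels)
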