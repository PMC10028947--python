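"""Core graph representation and stochastic normalization.

Graphs are plain :class:`networkx.Graph` objects: protein identifiers as
string nodes, undirected simple edges. Two attribute conventions are used
throughout the package:

* ``confidence`` (edge attribute) — non-negative interaction confidence on
  the StringDB 0–1000 scale, used only for ingest filtering;
* ``weight`` (node attribute) — positive per-node weight C_i, e.g. a gene
  expression value, consumed by the network-potential score.

The random walk operates on a column-stochastic transition matrix built
from the unweighted adjacency structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

CONFIDENCE = "confidence"
NODE_WEIGHT = "weight"

__all__ = [
    "CONFIDENCE",
    "NODE_WEIGHT",
    "TransitionMatrix",
    "build_graph",
    "to_transition_matrix",
    "induced_subgraph",
    "node_order",
]


def node_order(g: nx.Graph) -> tuple[str, ...]:
    """Canonical (lexicographic) node ordering used for all matrices."""
    return tuple(sorted(g.nodes))


def build_graph(
    edge_records: Iterable[tuple | Sequence],
) -> nx.Graph:
    """Build a simple undirected graph from ``(u, v[, confidence])`` records.

    Self-loops are dropped; duplicate edges (in either orientation) are
    collapsed keeping the maximum confidence seen.

    Raises
    ------
    ValueError
        If no usable (non-self-loop) edge remains.
    """
    g = nx.Graph()
    for rec in edge_records:
        if len(rec) == 2:
            u, v = rec
            conf = None
        else:
            u, v, conf = rec[0], rec[1], rec[2]
        u, v = str(u), str(v)
        if u == v:
            continue
        if g.has_edge(u, v):
            if conf is not None:
                prev = g.edges[u, v].get(CONFIDENCE)
                if prev is None or conf > prev:
                    g.edges[u, v][CONFIDENCE] = float(conf)
        else:
            if conf is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, **{CONFIDENCE: float(conf)})
    if g.number_of_edges() == 0:
        raise ValueError("no usable edges: input was empty or contained only self-loops")
    return g


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic random-walk operator over a fixed node ordering.

    ``matrix[i, j] = 1/deg(j)`` when node ``order[i]`` neighbours
    ``order[j]``, zero otherwise. Isolated nodes yield all-zero columns
    (walk mass never enters them; they are rejected as seeds upstream).
    """

    matrix: sp.csc_matrix
    order: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(
                self, "index", {v: i for i, v in enumerate(self.order)}
            )

    @property
    def n(self) -> int:
        return len(self.order)

    def isolated(self) -> frozenset[str]:
        """Nodes whose columns are all zero (degree 0)."""
        col_nnz = np.diff(self.matrix.indptr)
        return frozenset(v for v, k in zip(self.order, col_nnz) if k == 0)


def to_transition_matrix(g: nx.Graph) -> TransitionMatrix:
    """Normalize the adjacency matrix of ``g`` into a column-stochastic walk.

    Edge confidences are deliberately ignored: the walk is unweighted and a
    neighbour is chosen uniformly at random, so column ``j`` carries
    ``1/deg(j)`` at the rows of ``j``'s neighbours.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot build a transition matrix from an empty graph")
    order = node_order(g)
    adj = nx.to_scipy_sparse_array(g, nodelist=order, weight=None, format="csc")
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.zeros_like(deg, dtype=float)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    w = (adj.astype(float) @ sp.diags(inv)).tocsc()
    return TransitionMatrix(matrix=sp.csc_matrix(w), order=order)


def induced_subgraph(g: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``keep`` ∩ V(g); attributes are preserved.

    Identifiers absent from ``g`` are ignored with a warning reporting how
    many were dropped. An empty intersection is an error.
    """
    keep = set(keep)
    present = keep & set(g.nodes)
    missing = len(keep) - len(present)
    if missing:
        warnings.warn(
            f"induced_subgraph: {missing} requested node(s) not in graph; ignored",
            stacklevel=2,
        )
    if not present:
        raise ValueError("induced_subgraph: no requested node exists in the graph")
    return g.subgraph(present).copy()
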