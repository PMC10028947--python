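"""Node scoring methods and score-based graph filtration.

Four scores are provided: degree, raw expression value, betweenness
centrality, and the thermodynamic network potential

    G_i = C_i * ln( C_i / (C_i + sum_{j in N(i)} C_j) ),

where C_i > 0 is the node weight (typically log-scale expression) and N(i)
the neighbours of i. The log argument lies in (0, 1], so G_i <= 0, with
equality exactly for isolated nodes; the total S = sum_i G_i acts as a
free-energy-like global state of the weighted network.

``gfilter`` reduces a graph to the induced subgraph on the top-n (or
bottom-n) nodes under any of these scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import NODE_WEIGHT, induced_subgraph, node_order

__all__ = [
    "NodeScore",
    "network_potential",
    "betweenness",
    "degree_score",
    "gfilter",
    "gfilter_by_value",
]

_METHODS = ("degree", "value", "betweenness", "network_potential", "crosstalk_affinity")


@dataclass
class NodeScore:
    """A named per-node score vector covering (a subset of) a graph."""

    method: str
    scores: pd.Series

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown scoring method {self.method!r}")


def _weights_for(g: nx.Graph, weights: pd.Series) -> pd.Series:
    order = list(node_order(g))
    missing = [v for v in order if v not in weights.index]
    bad = [v for v in order if v in weights.index and not weights[v] > 0]
    if missing or bad:
        raise ValueError(
            "network potential requires a positive weight for every node; "
            f"missing: {sorted(missing)}; non-positive: {sorted(bad)}"
        )
    return weights.loc[order].astype(float)


def network_potential(g: nx.Graph, weights: pd.Series) -> NodeScore:
    """Gibbs-free-energy-like potential G_i for every node of ``g``.

    Every node must carry a strictly positive weight; filter the graph
    first (see :func:`gfilter_by_value`) if some nodes lack expression.
    """
    c = _weights_for(g, weights)
    order = list(c.index)
    adj = nx.to_scipy_sparse_array(g, nodelist=order, weight=None, format="csr")
    neighbour_sum = adj @ c.to_numpy()
    vals = c.to_numpy() * np.log(c.to_numpy() / (c.to_numpy() + neighbour_sum))
    return NodeScore(
        "network_potential",
        pd.Series(vals, index=pd.Index(order, name="node"), name="network_potential"),
    )


def betweenness(g: nx.Graph) -> NodeScore:
    """Unnormalized betweenness centrality over unordered node pairs.

    g(v) = sum over pairs {s, t}, s != v != t, of the fraction of shortest
    s–t paths that pass through v (unweighted shortest paths).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("betweenness of an empty graph is undefined")
    bc = nx.betweenness_centrality(g, normalized=False)
    return NodeScore(
        "betweenness",
        pd.Series(bc, name="betweenness").rename_axis("node").sort_index(),
    )


def degree_score(g: nx.Graph) -> NodeScore:
    return NodeScore(
        "degree",
        pd.Series(dict(g.degree), name="degree", dtype=float)
        .rename_axis("node")
        .sort_index(),
    )


def _ranked(scores: pd.Series, descending: bool) -> list[str]:
    # rank by score (direction per flag), ties broken by node id ascending:
    # sort by id first, then stable-sort by score
    df = scores.rename("s").rename_axis("node").reset_index()
    df = df.sort_values("node", kind="mergesort")
    df = df.sort_values("s", ascending=not descending, kind="mergesort")
    return df["node"].tolist()


def gfilter(g: nx.Graph, score: NodeScore, n: int, descending: bool = True) -> nx.Graph:
    """Induced subgraph on the n best-scoring nodes.

    Ties are broken by node id ascending; ``n >= |V|`` returns the graph
    unchanged (a copy).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nodes = set(g.nodes)
    uncovered = nodes - set(score.scores.index)
    if uncovered:
        raise ValueError(f"score does not cover node(s): {sorted(uncovered)}")
    if n >= g.number_of_nodes():
        return g.copy()
    keep = _ranked(score.scores.loc[sorted(nodes)], descending)[:n]
    return induced_subgraph(g, keep)


def gfilter_by_value(
    g: nx.Graph, values: pd.Series, n: int, descending: bool = True
) -> nx.Graph:
    """Filter by a user-supplied value vector (e.g. expression).

    Nodes without a value are excluded from ranking and from the result;
    surviving nodes carry their value as the ``weight`` node attribute.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scored = sorted(set(g.nodes) & set(values.index))
    if not scored:
        raise ValueError("no node of the graph has a value; nothing to rank")
    keep = _ranked(values.loc[scored], descending)[: min(n, len(scored))]
    sub = induced_subgraph(g, keep)
    nx.set_node_attributes(sub, values.loc[keep].to_dict(), NODE_WEIGHT)
    return sub
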