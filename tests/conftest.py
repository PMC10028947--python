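import networkx as nx
import pandas as pd
import pytest

from ppiwalk import build_graph


@pytest.fixture
def path_graph():
    """A–B–C path."""
    return build_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    return build_graph([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def star6():
    """Star with hub H and 6 leaves."""
    return build_graph([("H", f"L{i}") for i in range(1, 7)])


@pytest.fixture
def two_cliques():
    """Two disjoint 4-cliques {A1..A4} and {B1..B4}."""
    g = nx.Graph()
    for prefix in ("A", "B"):
        names = [f"{prefix}{i}" for i in range(1, 5)]
        g.add_edges_from(nx.complete_graph(names).edges)
    return g


@pytest.fixture
def unit_weights():
    def make(g):
        return pd.Series(1.0, index=sorted(g.nodes))

    return make
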