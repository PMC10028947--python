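"""Seeded synthetic graphs and expression vectors for tests and demos.

Every generator is a pure function of its spec: the same
``(model, n_nodes, param, rng_seed)`` always yields the same graph, and the
same spec yields the same expression vector. Node ids are zero-padded
("G0001", ...). Expression is drawn from a lognormal law — strictly
positive and right-skewed, emulating log-scale gene expression — so the
network-potential preconditions are always satisfiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import CONFIDENCE, node_order
from .io import BIOGRID_COL_A, BIOGRID_COL_B

__all__ = ["FixtureSpec", "make_graph", "make_expression", "write_fixture_files"]

MODELS = ("erdos_renyi", "barabasi_albert", "ring", "star", "two_cliques")

#: confidence written for edges that carry none (StringDB dialect needs one)
DEFAULT_CONFIDENCE = 999


@dataclass(frozen=True)
class FixtureSpec:
    model: str = "erdos_renyi"
    n_nodes: int = 50
    param: float | int | None = None
    rng_seed: int = 0
    expression_mu: float = 2.0
    expression_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown graph model {self.model!r}; choose from {MODELS}")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")


def _node_name(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"G{i + 1:0{width}d}"


def make_graph(spec: FixtureSpec) -> nx.Graph:
    """Deterministic synthetic graph for the given spec."""
    n = spec.n_nodes
    if spec.model == "erdos_renyi":
        p = 0.1 if spec.param is None else float(spec.param)
        g = nx.gnp_random_graph(n, p, seed=spec.rng_seed)
    elif spec.model == "barabasi_albert":
        m = 3 if spec.param is None else int(spec.param)
        g = nx.barabasi_albert_graph(n, m, seed=spec.rng_seed)
    elif spec.model == "ring":
        g = nx.cycle_graph(n)
    elif spec.model == "star":
        g = nx.star_graph(n - 1)  # node 0 is the hub
    else:  # two_cliques
        half = n // 2
        g = nx.disjoint_union(nx.complete_graph(half), nx.complete_graph(n - half))
    mapping = {i: _node_name(i, n) for i in g.nodes}
    return nx.relabel_nodes(g, mapping)


def make_expression(spec: FixtureSpec, g: nx.Graph) -> pd.Series:
    """One strictly positive lognormal draw per node, reproducible."""
    order = list(node_order(g))
    rng = np.random.default_rng([spec.rng_seed, 1])
    vals = rng.lognormal(mean=spec.expression_mu, sigma=spec.expression_sigma, size=len(order))
    return pd.Series(vals, index=pd.Index(order, name="node"), name="value")


def write_fixture_files(
    g: nx.Graph,
    e: pd.Series,
    dialect: str,
    out_dir: Path,
    species_code: str = "9606",
) -> Path:
    """Emit a small file in one supported dialect; parses back identically.

    ``stringdb`` and ``biogrid`` write the graph, ``expression`` writes the
    vector. Returns the file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dialect == "stringdb":
        path = out_dir / "fixture_stringdb_links.txt"
        with open(path, "w") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for u, v, data in sorted(g.edges(data=True)):
                a, b = (u, v) if u <= v else (v, u)
                conf = data.get(CONFIDENCE, DEFAULT_CONFIDENCE)
                fh.write(f"{species_code}.{a} {species_code}.{b} {conf:g}\n")
    elif dialect == "biogrid":
        path = out_dir / "fixture_biogrid.tab.txt"
        with open(path, "w") as fh:
            fh.write(f"#ID A\t#ID B\t{BIOGRID_COL_A}\t{BIOGRID_COL_B}\n")
            for k, (u, v) in enumerate(sorted(g.edges())):
                a, b = (u, v) if u <= v else (v, u)
                fh.write(f"{2 * k}\t{2 * k + 1}\t{a}\t{b}\n")
    elif dialect == "expression":
        path = out_dir / "fixture_expression.tsv"
        with open(path, "w") as fh:
            fh.write("identifier\tvalue\n")
            for node, val in e.sort_index().items():
                fh.write(f"{node}\t{float(val)!r}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path
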