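"""Seed-anchored subnetwork identification with a degree-matched null.

``compute_crosstalk`` runs an RWR from the user's seed proteins, then
re-runs it from many random seed sets whose degrees resemble the observed
seeds' (degree-matched bootstrap), and keeps the nodes whose observed
affinity is significantly higher than their own null distribution.

Degree matching uses logarithmic bins, bin(v) = floor(log2(deg v)): a seed
of degree 100 may be replaced by any non-seed node of degree 64–127.
Exact-degree matching would starve bins on sparse graphs.

Empirical p-values use the add-one permutation correction
p = (1 + #{null >= observed}) / (1 + B), so p is never exactly zero from a
finite bootstrap; an adjusted p printed as 0 elsewhere corresponds to
p < 1/(B+1) here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .graph import TransitionMatrix, induced_subgraph, to_transition_matrix
from .rwr import AffinityVector, RwrParams, random_walk

__all__ = [
    "NullModel",
    "sample_null_seeds",
    "empirical_pvalues",
    "adjust_pvalues",
    "compute_crosstalk",
    "top_fraction",
]

_ADJUST_METHODS = {
    "BH": "fdr_bh",
    "fdr": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
}


@dataclass(frozen=True)
class NullModel:
    """Bootstrap configuration for the degree-matched null."""

    n_bootstrap: int = 1000
    rng_seed: int = 0
    degree_bin_rule: str = "log2"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.degree_bin_rule != "log2":
            raise ValueError(f"unknown degree_bin_rule {self.degree_bin_rule!r}")


def degree_bin(deg: int) -> int:
    """log2 bin index; degree-0 nodes get their own bin below all others."""
    return int(math.floor(math.log2(deg))) if deg > 0 else -1


def sample_null_seeds(
    g: nx.Graph, observed_seeds, null: NullModel
) -> list[frozenset[str]]:
    """Draw ``n_bootstrap`` degree-matched random seed sets.

    Each observed seed is replaced by a non-seed node from the same log2
    degree bin, uniformly and without replacement within one set. Replicate
    b derives its RNG stream from (rng_seed, b), so results are independent
    of execution order.
    """
    observed = frozenset(str(s) for s in observed_seeds)
    degrees = dict(g.degree)
    bins: dict[int, list[str]] = {}
    for v in sorted(g.nodes):
        if v in observed:
            continue
        bins.setdefault(degree_bin(degrees[v]), []).append(v)
    seed_bins = []
    for s in sorted(observed):
        if s not in degrees:
            raise ValueError(f"observed seed {s!r} is not in the graph")
        b = degree_bin(degrees[s])
        if not bins.get(b):
            raise ValueError(
                f"no degree-matched candidate for seed {s!r} "
                f"(degree {degrees[s]}, log2 bin {b})"
            )
        seed_bins.append((s, b))
    out: list[frozenset[str]] = []
    for rep in range(null.n_bootstrap):
        rng = np.random.default_rng([null.rng_seed, rep])
        available = {b: list(members) for b, members in bins.items()}
        chosen: list[str] = []
        for s, b in seed_bins:
            pool = available[b]
            if not pool:
                raise ValueError(
                    f"degree bin {b} exhausted while matching seed {s!r}; "
                    "too few candidates for without-replacement sampling"
                )
            k = int(rng.integers(len(pool)))
            chosen.append(pool.pop(k))
        out.append(frozenset(chosen))
    return out


def empirical_pvalues(observed: AffinityVector, null_affinities: pd.DataFrame) -> pd.Series:
    """Add-one permutation p-value per node against its own null draws.

    ``null_affinities`` holds one row per node and one column per bootstrap
    replicate; ties count against the observed score (>= comparison).
    """
    obs = observed.scores
    if not obs.index.equals(null_affinities.index):
        if set(obs.index) != set(null_affinities.index):
            raise ValueError("observed and null affinity node sets differ")
        null_affinities = null_affinities.loc[obs.index]
    if null_affinities.isna().any().any():
        raise ValueError("every node needs the same number B of null draws")
    b = null_affinities.shape[1]
    exceed = (null_affinities.to_numpy() >= obs.to_numpy()[:, None]).sum(axis=1)
    return pd.Series((1.0 + exceed) / (1.0 + b), index=obs.index, name="p_value")


def adjust_pvalues(p: pd.Series, method: str = "BH") -> pd.Series:
    """Multiple-testing adjustment (BH step-up, Holm step-down, Bonferroni)."""
    if method not in _ADJUST_METHODS:
        raise ValueError(
            f"unknown adjustment method {method!r}; choose from {sorted(_ADJUST_METHODS)}"
        )
    arr = p.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method=_ADJUST_METHODS[method])
    return pd.Series(adj, index=p.index, name="adj_p_value")


def compute_crosstalk(
    g: nx.Graph,
    seeds,
    params: RwrParams | None = None,
    null: NullModel | None = None,
    significance_level: float = 0.05,
    p_adjust: str = "BH",
) -> tuple[pd.DataFrame, nx.Graph]:
    """Identify the subnetwork significantly associated with the seeds.

    Returns the result table (node, seed, affinity_score, p_value,
    adj_p_value; seeds first, then affinity descending, node id as
    tie-break) restricted to nodes with ``adj_p < significance_level``, and
    the induced subgraph on those nodes. An empty result is returned with a
    warning, not an error.
    """
    if params is None:
        params = RwrParams()
    if null is None:
        null = NullModel()
    seeds = frozenset(str(s) for s in seeds)
    w: TransitionMatrix = to_transition_matrix(g)
    observed = random_walk(w, seeds, params)
    null_sets = sample_null_seeds(g, seeds, null)
    null_mat = np.empty((w.n, len(null_sets)))
    for j, ns in enumerate(null_sets):
        null_mat[:, j] = random_walk(w, ns, params).scores.to_numpy()
    null_df = pd.DataFrame(null_mat, index=observed.scores.index)
    pvals = empirical_pvalues(observed, null_df)
    adj = adjust_pvalues(pvals, p_adjust)
    table = pd.DataFrame(
        {
            "node": observed.scores.index,
            "seed": [v in seeds for v in observed.scores.index],
            "affinity_score": observed.scores.to_numpy(),
            "p_value": pvals.to_numpy(),
            "adj_p_value": adj.to_numpy(),
        }
    )
    table = table[table["adj_p_value"] < significance_level]
    table = table.sort_values("node", kind="mergesort")
    table = table.sort_values("affinity_score", ascending=False, kind="mergesort")
    table = table.sort_values("seed", ascending=False, kind="mergesort")
    table = table.reset_index(drop=True)
    if table.empty:
        warnings.warn(
            f"no node reached adj_p < {significance_level}; returning empty result",
            stacklevel=2,
        )
        return table, nx.Graph()
    sub = induced_subgraph(g, table["node"])
    return table, sub


def top_fraction(table: pd.DataFrame, prop_keep: float) -> pd.DataFrame:
    """Keep the top fraction of result rows by affinity (plotting helper)."""
    if not 0.0 < prop_keep <= 1.0:
        raise ValueError("prop_keep must be in (0, 1]")
    k = max(1, int(math.ceil(prop_keep * len(table))))
    ranked = table.sort_values(
        ["affinity_score", "node"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)
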