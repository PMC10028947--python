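# Methods

## Graph model

Graphs are simple and undirected: protein identifiers as string nodes,
interactions as edges. Ingest (`build_graph`) drops self-interactions and
collapses duplicate rows in either orientation, keeping the maximum
confidence. Edge confidence (StringDB combined_score, 0–1000) is used only
to filter edges on ingest; the walk itself is **unweighted** — a walker at a
node picks a neighbour uniformly. Exposing a confidence-weighted walk would
be a one-line change, but mixing evidence scores into transition
probabilities changes the meaning of affinity and is deliberately not the
default.

Node ordering for every matrix is lexicographic over node ids and fixed at
construction, which makes all downstream output deterministic.

## Random walk with restarts

The transition operator is column-stochastic: `W[i, j] = 1/deg(j)` for
neighbours i of j. The walk iterates

    p_{t+1} = (1 − γ) W p_t + γ r,     p_0 = r,

with `r` uniform over the seed set. Choices and rationale:

* **γ (restart probability), default 0.6.** Each of k seeds retains at
  least γ/k of the mass, so γ controls how local the diffusion is; 0.6
  keeps the result tightly centred on the seed neighbourhood.
* **p₀ = r** makes the γ=1 limit exact after one iteration.
* **L1 stop rule, default eps = 1e-10, tmax = 200.** The iteration is a
  contraction with factor (1−γ), so for γ=0.6 the error shrinks ~0.4× per
  step and convergence takes a few dozen iterations; L1 matches the
  probability-mass semantics of p. The output records `converged` and
  `iterations_used`.
* **Isolated nodes** get all-zero columns and are rejected as seeds: an
  undirected isolated node has no in-edges, so the only way mass could rest
  there is via restart, and accepting such seeds would silently break the
  "p sums to 1" invariant.

`solve_rwr_exact` computes the stationary vector by a dense solve of
`(I − (1−γ)W) p = γ r` and exists as an independent oracle for testing; it
is guarded to ≤ 2000 nodes.

## Degree-matched bootstrap and p-values

Null seed sets replace each observed seed with a uniform draw from the
non-seed nodes in the same **log2 degree bin** (`floor(log2 deg)`), without
replacement within a set. Exact-degree matching starves bins in sparse
graphs; log2 bins keep the null degree profile close while guaranteeing
candidates in realistic networks. A bin with no candidate is an error — the
caller must either drop that seed or supply a denser graph; silently
relaxing the matching would bias the null.

Each node is compared against **its own** B null affinities (not a pooled
distribution): `p = (1 + #{null ≥ obs}) / (1 + B)`, the add-one permutation
correction, so p is never exactly 0 and a "p = 0" in other reports
corresponds to `p < 1/(B+1)` here. Ties count against the observed score.
Adjustment (BH by default, Holm and Bonferroni available) is delegated to
statsmodels; nodes with adjusted p **below** the significance level are
retained. Defaults B = 1000, α = 0.05.

Replicate b draws its RNG stream from the pair (rng_seed, b), so results
are reproducible and independent of execution order.

## Node scores

* **degree** — neighbour count.
* **betweenness** — unnormalized, unweighted shortest paths, each unordered
  pair {s, t} counted once (networkx implementation; an exhaustive
  path-enumeration oracle backs it in the tests).
* **value** — a user-supplied vector such as expression; nodes without a
  value are excluded from ranking rather than zero-filled.
* **network_potential** — `G_i = C_i ln(C_i / (C_i + Σ_{j∈N(i)} C_j))`
  with weights C_i > 0. The denominator includes C_i itself, which keeps
  the log argument in (0, 1] and hence G_i ≤ 0, consistent with the
  free-energy interpretation; an isolated node has G = 0 exactly. Nodes
  with missing or non-positive weight are an error: on a log scale,
  zero-filling is meaningless, so callers drop those nodes first
  (`gfilter_by_value` does this and attaches the weights).

Expression is loaded as `log2(E + 1)`: the pseudocount keeps zero counts
finite where a literal log2 would produce −inf. The flag `log2_transform`
turns the transform off for pre-transformed data.

`gfilter` keeps the top-n (or bottom-n) nodes by any score, ties broken by
node id ascending, and returns the induced subgraph; n ≥ |V| is the
identity. Filtrations compose: a degree-then-expression reduction is two
calls.

## In-silico repression

For each target i: score all nodes (s_v), total S = Σ s_v, remove i,
re-score **only** the nodes affected — for network potential that is
exactly N(i), since s_j depends only on C_j and its neighbours' weights —
and record per-node deltas in column i of a sparse matrix. The diagonal
entry holds s_i itself (present in S, absent in S_i), making the column-sum
identity `Σ_j m[j,i] = ΔS_i = S − S_i` literal. The incremental path is the
module's central performance claim and is tested to 1e-12 against a naive
full-recompute oracle.

Ranking is by |ΔS| descending (removals make ΔS negative because the
potential is non-positive), with the signed value always reported and node
id as tie-break.

The topology null generates degree-preserving rewired graphs by double edge
swaps: `ceil(swap_multiplier · |E|)` swap *attempts* (default multiplier
10, a standard burn-in), each rejected if it would create a self-loop or
duplicate edge. Counting attempts rather than successes means graphs that
admit no valid swap (a triangle, a single edge) return unchanged with a
warning instead of looping or raising. Node weights stay attached to node
identities — only topology is randomized. Per-target
`p = (1 + #{|ΔS_null| ≥ |ΔS_obs|}) / (1 + n_rewires)`.

Only network potential ships as a state function; `node_repression` is
structured around a scores-from-(graph, weights) computation so other state
functions can slot in later.

## Synthetic fixtures

The fixture generator produces the graphs and expression vectors all tests
and examples run on: Erdős–Rényi, Barabási–Albert, ring, star, and a
two-clique graph (two disconnected complete halves, useful for
unreachability checks). Expression is lognormal (defaults μ = 2, σ = 1) —
strictly positive and right-skewed like log-scale expression data.
Generators are pure functions of their spec, bitwise reproducible.

What the fixtures do **not** emulate: the size (10⁴ nodes, 10⁶ edges),
degree correlations, clustering and annotation biases of curated PPI
networks, or correlated real expression. Passing tests therefore establish
algorithmic correctness and calibration on known topologies, not biological
conclusions about any particular interactome.

## Verification problem sizes

The acceptance script and test suite run at desk scale, chosen so the whole
suite completes in seconds while still exercising every contract: 50 random
graphs up to 200 nodes for the RWR/dense-solve comparison (agreement within
1e-8 L∞ at eps = 1e-14), a 200-node scale-free graph with B = 99 and 50
replicates for p-value calibration, 100 graphs ≤ 12 nodes for the
exhaustive betweenness oracle, 50 weighted graphs ≤ 30 nodes for the
incremental-repression contract (1e-12), and 100 rewiring trials for degree
preservation.

## Known limitations

* Walks are unweighted; confidence-weighted transitions are out of scope.
* Per-node nulls on very small graphs are conservative: with few candidate
  nodes, a non-seed node often appears in the null seed sets, inflating its
  own null distribution. Seed-specific subnetworks sharpen as the graph
  grows relative to the seed set.
* The empirical p floor is 1/(B+1); multiplicity-corrected discovery at
  α = 0.05 over n nodes needs B on the order of n/α draws.
* BioGRID auto-download is not configured (pass a local file); StringDB
  fetching requires network access and is bypassed entirely by the cache or
  local files.
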