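import numpy as np
import pandas as pd
import pytest

from ppiwalk import (
    NullModel,
    RwrParams,
    adjust_pvalues,
    build_graph,
    compute_crosstalk,
    empirical_pvalues,
    sample_null_seeds,
    to_transition_matrix,
    top_fraction,
)
from ppiwalk.fixtures import FixtureSpec, make_graph
from ppiwalk.rwr import AffinityVector, random_walk


def bh_oracle(pvals):
    """Textbook step-up BH definition, implemented independently."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        i = m - rank_from_top  # 1-based rank of this p in ascending order
        val = min(prev, pvals[idx] * m / i)
        adj[idx] = val
        prev = val
    return adj


def _affinity(series, seeds=("S",)):
    return AffinityVector(
        scores=series, seed_set=frozenset(seeds), converged=True, iterations_used=1
    )


class TestSampleNullSeeds:
    def test_regular_graph_excludes_seed(self):
        g = make_graph(FixtureSpec(model="ring", n_nodes=8))
        seed = sorted(g.nodes)[0]
        sets = sample_null_seeds(g, {seed}, NullModel(n_bootstrap=3, rng_seed=7))
        assert len(sets) == 3
        for s in sets:
            assert len(s) == 1 and seed not in s

    def test_forced_draw_single_candidate(self):
        # hub degree 4; leaves degree 1 except X which also has degree 4
        g = build_graph(
            [("H", "L1"), ("H", "L2"), ("H", "L3"), ("H", "X"),
             ("X", "L1"), ("X", "L2"), ("X", "L3")]
        )
        [only] = sample_null_seeds(g, {"H"}, NullModel(n_bootstrap=1, rng_seed=0))
        assert only == {"X"}

    def test_deterministic_from_seed(self):
        g = make_graph(FixtureSpec(model="barabasi_albert", n_nodes=60, param=2, rng_seed=3))
        seeds = set(sorted(g.nodes)[-3:])  # late arrivals: low degree, full bins
        a = sample_null_seeds(g, seeds, NullModel(n_bootstrap=5, rng_seed=11))
        b = sample_null_seeds(g, seeds, NullModel(n_bootstrap=5, rng_seed=11))
        assert a == b

    def test_degree_bins_match(self):
        g = make_graph(FixtureSpec(model="barabasi_albert", n_nodes=80, param=2, rng_seed=5))
        deg = dict(g.degree)
        # two seeds from a well-populated degree bin
        by_bin = {}
        for v in sorted(g.nodes):
            by_bin.setdefault(int(np.floor(np.log2(deg[v]))), []).append(v)
        members = max(by_bin.values(), key=len)
        seeds = set(members[:2])
        sets = sample_null_seeds(g, seeds, NullModel(n_bootstrap=20, rng_seed=1))
        seed_bins = sorted(int(np.floor(np.log2(deg[s]))) for s in seeds)
        for s in sets:
            bins = sorted(int(np.floor(np.log2(deg[v]))) for v in s)
            assert bins == seed_bins

    def test_empty_bin_errors(self, star6):
        # the hub (degree 6) has no non-seed candidate in its log2 bin
        with pytest.raises(ValueError, match="degree 6"):
            sample_null_seeds(star6, {"H"}, NullModel(n_bootstrap=1, rng_seed=0))

    def test_b_zero_rejected(self):
        with pytest.raises(ValueError, match="n_bootstrap"):
            NullModel(n_bootstrap=0)


class TestEmpiricalPvalues:
    def test_observed_above_all_nulls(self):
        obs = _affinity(pd.Series({"A": 0.9}))
        nulls = pd.DataFrame(np.full((1, 99), 0.1), index=["A"])
        p = empirical_pvalues(obs, nulls)
        assert p["A"] == pytest.approx(1 / 100)

    def test_observed_below_all_nulls(self):
        obs = _affinity(pd.Series({"A": 0.0}))
        nulls = pd.DataFrame(np.full((1, 99), 0.1), index=["A"])
        assert empirical_pvalues(obs, nulls)["A"] == 1.0

    def test_ties_count_against(self):
        obs = _affinity(pd.Series({"A": 0.5}))
        row = np.array([0.5] * 5 + [0.1] * 5)
        nulls = pd.DataFrame(row[None, :], index=["A"])
        assert empirical_pvalues(obs, nulls)["A"] == pytest.approx(6 / 11)

    def test_node_set_mismatch_errors(self):
        obs = _affinity(pd.Series({"A": 0.5, "B": 0.5}))
        nulls = pd.DataFrame(np.zeros((1, 3)), index=["A"])
        with pytest.raises(ValueError):
            empirical_pvalues(obs, nulls)


class TestAdjustPvalues:
    def test_single_p_bonferroni_unchanged(self):
        p = pd.Series({"A": 0.04})
        assert adjust_pvalues(p, "bonferroni")["A"] == pytest.approx(0.04)

    def test_bonferroni_scales_by_m(self):
        p = pd.Series({"A": 0.01, "B": 0.02, "C": 0.03})
        adj = adjust_pvalues(p, "bonferroni")
        assert np.allclose(adj, [0.03, 0.06, 0.09])

    def test_bh_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            raw = rng.uniform(size=rng.integers(1, 40))
            p = pd.Series(raw, index=[f"N{i}" for i in range(len(raw))])
            adj = adjust_pvalues(p, "BH")
            assert np.allclose(adj.to_numpy(), bh_oracle(raw), atol=1e-12)

    def test_bh_spec_example(self):
        p = pd.Series([0.01, 0.02, 0.04, 0.04])
        adj = adjust_pvalues(p, "BH")
        assert np.allclose(adj.to_numpy(), bh_oracle(p.to_numpy()))

    @pytest.mark.parametrize("method", ["BH", "bonferroni", "holm"])
    def test_adjusted_at_least_raw(self, method):
        rng = np.random.default_rng(7)
        p = pd.Series(rng.uniform(size=25))
        adj = adjust_pvalues(p, method)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            adjust_pvalues(pd.Series([0.5]), "fishing")


class TestComputeCrosstalk:
    def test_star_center_seed_retained_first(self):
        g = make_graph(FixtureSpec(model="star", n_nodes=12))
        hub = [v for v, d in g.degree if d == 11][0]
        leaf = sorted(set(g.nodes) - {hub})[0]
        table, sub = compute_crosstalk(
            g,
            {leaf},
            params=RwrParams(),
            null=NullModel(n_bootstrap=50, rng_seed=0),
            significance_level=0.5,
        )
        assert (table["affinity_score"].iloc[0] == table["affinity_score"].max())
        assert bool(table["seed"].iloc[0]) is True
        assert table["node"].iloc[0] == leaf

    def test_disconnected_clique_never_retained(self, two_cliques):
        table, sub = compute_crosstalk(
            two_cliques,
            {"A1"},
            null=NullModel(n_bootstrap=30, rng_seed=2),
            significance_level=0.99,
        )
        assert not any(n.startswith("B") for n in table["node"])
        assert not any(n.startswith("B") for n in sub.nodes)

    def test_result_rows_match_subgraph(self):
        g = make_graph(FixtureSpec(model="barabasi_albert", n_nodes=50, param=2, rng_seed=9))
        seeds = set(sorted(g.nodes)[:2])
        table, sub = compute_crosstalk(
            g, seeds, null=NullModel(n_bootstrap=30, rng_seed=5), significance_level=0.3
        )
        assert set(table["node"]) == set(sub.nodes)
        assert (table["adj_p_value"] >= table["p_value"] - 1e-15).all()
        assert (table["adj_p_value"] < 0.3).all()

    def test_deterministic(self):
        g = make_graph(FixtureSpec(model="barabasi_albert", n_nodes=40, param=2, rng_seed=1))
        seeds = set(sorted(g.nodes)[:2])
        t1, _ = compute_crosstalk(g, seeds, null=NullModel(n_bootstrap=20, rng_seed=3))
        t2, _ = compute_crosstalk(g, seeds, null=NullModel(n_bootstrap=20, rng_seed=3))
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_result_warns(self, two_cliques):
        with pytest.warns(UserWarning, match="empty"):
            table, sub = compute_crosstalk(
                two_cliques,
                {"A1"},
                null=NullModel(n_bootstrap=10, rng_seed=0),
                significance_level=1e-9,
            )
        assert table.empty and sub.number_of_nodes() == 0

    def test_pvalue_calibration_under_null(self):
        # seeds drawn the same way as the null ensemble: p should be ~uniform
        g = make_graph(FixtureSpec(model="barabasi_albert", n_nodes=100, param=3, rng_seed=0))
        w = to_transition_matrix(g)
        deg = dict(g.degree)
        bins = {}
        for v in sorted(g.nodes):
            bins.setdefault(int(np.floor(np.log2(deg[v]))), []).append(v)
        pool = sorted(v for mem in bins.values() if len(mem) >= 8 for v in mem)
        b = 49
        fracs = []
        rng = np.random.default_rng(123)
        for rep in range(10):
            seeds = set(rng.choice(pool, size=4, replace=False))
            obs = random_walk(w, seeds)
            null_sets = sample_null_seeds(g, seeds, NullModel(n_bootstrap=b, rng_seed=rep))
            mat = np.column_stack(
                [random_walk(w, ns).scores.to_numpy() for ns in null_sets]
            )
            p = empirical_pvalues(obs, pd.DataFrame(mat, index=obs.scores.index))
            non_seed = p.drop(list(seeds))
            fracs.append((non_seed <= 0.1).mean())
        alpha = 0.1
        assert np.mean(fracs) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / b)


class TestTopFraction:
    def test_keeps_ceiling_fraction(self):
        table = pd.DataFrame(
            {"node": list("ABCDE"), "affinity_score": [0.5, 0.4, 0.3, 0.2, 0.1]}
        )
        kept = top_fraction(table, 0.4)
        assert list(kept["node"]) == ["A", "B"]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            top_fraction(pd.DataFrame({"node": [], "affinity_score": []}), 0.0)
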