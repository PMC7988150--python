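"""Correlation-graph thresholds and MCODE kernel detection."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pmikit import (
    GeneSet,
    MCODEParams,
    TimeCourseMatrix,
    correlation_graph,
    correlation_pvalue,
    mcode_find_clusters,
    mcode_vertex_weights,
    summarize_cluster,
)
from pmikit.network import Cluster


def kcore_bruteforce_weight(adj: dict, v):
    """Independent MCODE weight oracle: highest k-core of N[v] by repeated
    pruning over plain dict adjacency, then k * density."""
    nodes = set(adj[v]) | {v}
    if len(nodes) == 1:
        return 0.0
    sub = {u: set(adj[u]) & nodes for u in nodes}
    best_k, best_nodes = 0, None
    k = 1
    while True:
        cur = {u: set(n) for u, n in sub.items()}
        changed = True
        while changed:
            changed = False
            for u in list(cur):
                if len(cur[u]) < k:
                    for w in cur[u]:
                        cur[w].discard(u)
                    del cur[u]
                    changed = True
        if not cur:
            break
        best_k, best_nodes = k, set(cur)
        k += 1
    edges = sum(len(set(adj[u]) & best_nodes) for u in best_nodes) / 2
    m = len(best_nodes)
    density = edges / (m * (m - 1) / 2)
    return best_k * density


def graph_to_adj(g):
    return {v: set(g.neighbors(v)) for v in g.nodes}


def make_tc(profiles: dict, timepoints=(0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)):
    df = pd.DataFrame.from_dict(profiles, orient="index", columns=list(timepoints))
    return TimeCourseMatrix(df)


class TestCorrelationPvalue:
    def test_positive_tail_below_edge_alpha(self):
        # the thresholds r > 0.95 and p < 0.001 at n = 7 are mutually
        # consistent for the positive-tail test used by the edge rule
        assert correlation_pvalue(0.95, 7) == pytest.approx(5.2254e-4, rel=1e-3)
        assert correlation_pvalue(0.95, 7) < 0.001

    def test_two_sided_value(self):
        assert correlation_pvalue(0.95, 7, alternative="two-sided") == pytest.approx(
            1.0451e-3, rel=1e-3)

    def test_monte_carlo_cross_check(self):
        """Permutation-style check: tail mass of sample r for iid normal
        pairs at n = 7 matches the t-transform."""
        rng = np.random.default_rng(12)
        reps = 120_000
        x = rng.standard_normal((reps, 7))
        y = rng.standard_normal((reps, 7))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        mc_one = float(np.mean(r >= 0.95))
        p = correlation_pvalue(0.95, 7)
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(mc_one - p) < 4 * se

    def test_perfect_correlation(self):
        assert correlation_pvalue(1.0, 7) == 0.0


class TestCorrelationGraph:
    def test_identical_profiles_link(self):
        tc = make_tc({"GA": [1, 2, 4, 8, 16, 32, 64], "GB": [2, 4, 8, 16, 32, 64, 128]})
        cg = correlation_graph(tc, pseudocount=0.0)
        assert cg.graph.has_edge("GA", "GB")
        assert cg.graph.edges["GA", "GB"]["r"] == pytest.approx(1.0)

    def test_antiphase_profiles_do_not_link(self):
        tc = make_tc({"GA": [64, 32, 16, 8, 4, 2, 1], "GB": [1, 2, 4, 8, 16, 32, 64]})
        cg = correlation_graph(tc)
        assert not cg.graph.has_edge("GA", "GB")

    def test_every_edge_satisfies_both_thresholds(self, small_timecourse):
        tc, _ = small_timecourse
        cg = correlation_graph(tc)
        assert cg.n_edges > 0
        for _, _, d in cg.graph.edges(data=True):
            assert d["r"] > cg.r_min
            assert d["p"] < cg.p_max

    def test_zero_variance_gene_excluded_with_warning(self):
        tc = make_tc({"GA": [1, 2, 4, 8, 16, 32, 64], "GB": [5, 5, 5, 5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            cg = correlation_graph(tc, pseudocount=0.0)
        assert "GB" not in cg.graph

    def test_candidate_subset_respected(self, small_timecourse):
        tc, truth = small_timecourse
        panel = GeneSet("panel", frozenset(g.gene_id for g in truth[:50]))
        cg = correlation_graph(tc, candidate_genes=panel)
        assert set(cg.graph.nodes) <= set(panel.members)


class TestVertexWeights:
    def test_triangle(self):
        g = nx.complete_graph(["a", "b", "c"])
        assert mcode_vertex_weights(g) == {"a": 2.0, "b": 2.0, "c": 2.0}

    def test_five_clique(self):
        g = nx.complete_graph(["a", "b", "c", "d", "e"])
        w = mcode_vertex_weights(g)
        assert all(v == pytest.approx(4.0) for v in w.values())

    def test_path_middle_vertex(self):
        g = nx.path_graph(["a", "b", "c"])
        w = mcode_vertex_weights(g)
        assert w["b"] == pytest.approx(2.0 / 3.0)
        assert w["a"] == pytest.approx(1.0)  # K2 neighbourhood

    def test_isolated_vertex(self):
        g = nx.Graph()
        g.add_node("solo")
        assert mcode_vertex_weights(g)["solo"] == 0.0

    def test_against_bruteforce_oracle_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 31))
            p = float(rng.uniform(0.1, 0.6))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            w = mcode_vertex_weights(g)
            adj = graph_to_adj(g)
            for v in g.nodes:
                assert w[v] == pytest.approx(kcore_bruteforce_weight(adj, v), abs=1e-12)


class TestClusterFinding:
    def test_two_disjoint_cliques(self):
        g = nx.union(
            nx.complete_graph([f"a{i}" for i in range(5)]),
            nx.complete_graph([f"b{i}" for i in range(5)]),
        )
        clusters = mcode_find_clusters(g)
        assert len(clusters) == 2
        assert sorted(len(c) for c in clusters) == [5, 5]

    def test_pendant_vertex_removed(self):
        g = nx.complete_graph([f"a{i}" for i in range(5)])
        g.add_edge("a0", "pendant")
        clusters = mcode_find_clusters(g)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(f"a{i}" for i in range(5))

    def test_empty_graph(self):
        assert mcode_find_clusters(nx.Graph()) == []

    def test_disjoint_and_contained(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = nx.gnp_random_graph(40, 0.15, seed=int(rng.integers(0, 2**31)))
            clusters = mcode_find_clusters(g)
            seen = set()
            for c in clusters:
                assert not (c.members & seen)
                assert c.members <= set(g.nodes)
                assert len(c) >= 2
                assert nx.is_connected(g.subgraph(c.members))
                seen |= c.members

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="vwp"):
            mcode_find_clusters(nx.complete_graph(3), MCODEParams(vwp=1.5))

    def test_deterministic_ordering(self):
        g = nx.union(
            nx.complete_graph([f"a{i}" for i in range(4)]),
            nx.complete_graph([f"b{i}" for i in range(4)]),
        )
        c1 = mcode_find_clusters(g)
        c2 = mcode_find_clusters(g)
        assert [c.members for c in c1] == [c.members for c in c2]
        # equal score: tie broken by smallest member id
        assert min(c1[0].members) < min(c1[1].members)


class TestSummarize:
    def test_flat_members_unit_profile(self):
        tc = make_tc({"GA": [5] * 7, "GB": [9] * 7})
        c = Cluster(members=frozenset({"GA", "GB"}), seed_gene="GA", score=1.0)
        out = summarize_cluster(tc, c)
        assert np.allclose(out.mean_profile, 1.0)
        assert np.allclose(out.profile_sem, 0.0)

    def test_equal_weights_match_unweighted(self):
        tc = make_tc({
            "GA": [10, 12, 14, 18, 26, 30, 40],
            "GB": [10, 11, 16, 20, 24, 32, 44],
        })
        c = Cluster(members=frozenset({"GA", "GB"}), seed_gene="GA", score=1.0)
        out = summarize_cluster(tc, c, weight_scheme="uniform", pseudocount=0.0)
        profiles = tc.values / tc.values[:, [0]]
        assert np.allclose(out.mean_profile, profiles.mean(axis=0))
        expected_sem = profiles.std(axis=0, ddof=1) / np.sqrt(2)
        assert np.allclose(out.profile_sem, expected_sem)

    def test_weighted_mean_hand_example(self):
        # weights 1 and 3, time-0-normalized profiles [1, 2] and [1, 4]:
        # weighted mean at 24 h = (1*2 + 3*4) / 4 = 3.5
        tc = make_tc({"GA": [8.0, 16.0], "GB": [8.0, 32.0]}, timepoints=(0.0, 24.0))
        c = Cluster(members=frozenset({"GA", "GB"}), seed_gene="GA", score=1.0)
        out = summarize_cluster(tc, c, weights={"GA": 1.0, "GB": 3.0},
                                weight_scheme="vertex_weight", pseudocount=0.0)
        assert out.mean_profile[1] == pytest.approx(3.5)

    def test_direction_labels(self):
        rising = make_tc({f"R{i}": [1, 1.5, 2, 3, 4, 5, 6] for i in range(3)})
        falling = make_tc({f"F{i}": [6, 5, 4, 3, 2, 1.5, 1] for i in range(3)})
        cr = Cluster(members=frozenset(rising.gene_ids), seed_gene="R0", score=1.0)
        cf = Cluster(members=frozenset(falling.gene_ids), seed_gene="F0", score=1.0)
        assert summarize_cluster(rising, cr).direction == "rising"
        assert summarize_cluster(falling, cf).direction == "falling"

    def test_missing_member_rejected(self, tiny_timecourse):
        c = Cluster(members=frozenset({"GA", "NOPE"}), seed_gene="GA", score=1.0)
        with pytest.raises(KeyError, match="NOPE"):
            summarize_cluster(tiny_timecourse, c)


def test_module_recovery_single_seed(small_cfg, small_timecourse):
    """Planted falling and rising modules come back as the two top kernels."""
    tc, truth = small_timecourse
    cg = correlation_graph(tc)
    w = mcode_vertex_weights(cg)
    clusters = mcode_find_clusters(cg, weights=w)
    clusters = [summarize_cluster(tc, c, weights=w) for c in clusters[:2]]
    neu = {g.gene_id for g in truth if g.planted_class == "neuronal_decay"}
    gli = {g.gene_id for g in truth if g.planted_class == "glial_rise"}
    jacc = {}
    for c in clusters:
        jn = len(c.members & neu) / len(c.members | neu)
        jg = len(c.members & gli) / len(c.members | gli)
        if jn >= jg:
            jacc["falling"] = (jn, c.direction)
        else:
            jacc["rising"] = (jg, c.direction)
    assert jacc["falling"][1] == "falling"
    assert jacc["rising"][1] == "rising"
    assert jacc["falling"][0] >= 0.7
    assert jacc["rising"][0] >= 0.7
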