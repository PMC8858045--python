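import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modulenet import netstats, synth
from modulenet.io import GeneSetCollection


def floyd_warshall_means(g, sources, targets):
    """Mean shortest path from each source to reachable targets (oracle)."""
    dist = dict(nx.all_pairs_shortest_path_length(g))
    out = {}
    for s in sources:
        ds = [dist[s][t] for t in targets if t != s and t in dist[s]]
        out[s] = np.mean(ds) if ds else np.nan
    return out


class TestInduceSubnetwork:
    def test_triangle_reduces_to_edge(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        sub, dropped = netstats.induce_subnetwork(g, {"A", "B"})
        assert set(sub.edges()) == {("A", "B")} or set(sub.edges()) == {("B", "A")}
        assert dropped == 0

    def test_no_internal_edges_is_error(self):
        g = nx.path_graph(["A", "x", "B"])
        with pytest.raises(ValueError, match="no edges"):
            netstats.induce_subnetwork(g, {"A", "B"})

    def test_matches_brute_force_edge_filter(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        g = nx.relabel_nodes(g, str)
        genes = {str(i) for i in rng.choice(30, 15, replace=False)}
        expected = {
            frozenset(e) for e in g.edges() if e[0] in genes and e[1] in genes
        }
        if not expected:
            pytest.skip("random instance has no internal edges")
        sub, _ = netstats.induce_subnetwork(g, genes)
        assert {frozenset(e) for e in sub.edges()} == expected


class TestDegreeRank:
    def test_star_center_first(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, lambda n: f"N{n}")
        rank = netstats.degree_rank(g)
        assert rank.index[0] == "N0" and rank.iloc[0] == 5

    def test_ties_break_alphabetically(self):
        g = nx.Graph([("b", "x"), ("b", "y"), ("b", "z"), ("a", "x"), ("a", "y"), ("a", "z")])
        rank = netstats.degree_rank(g)
        assert list(rank.index[:2]) == ["a", "b"]

    def test_degrees_match_neighbor_counts(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        rank = netstats.degree_rank(g)
        for node, score in rank.items():
            assert score == len(list(g.neighbors(node)))


class TestPrerankedGsea:
    def _ranks(self, n=20):
        return pd.Series(
            np.arange(n, 0, -1, dtype=float), index=[f"G{i:02d}" for i in range(n)]
        )

    def test_top_gene_set_has_es_one(self):
        ranks = self._ranks()
        coll = GeneSetCollection(sets={"top": {ranks.index[0]}})
        tab = netstats.preranked_gsea(ranks, coll, n_perm=50, seed=1)
        assert tab.es.iloc[0] == pytest.approx(1.0)

    def test_bottom_gene_unweighted_es_minus_one(self):
        ranks = self._ranks()
        coll = GeneSetCollection(sets={"bottom": {ranks.index[-1]}})
        tab = netstats.preranked_gsea(ranks, coll, n_perm=50, weight_p=0.0, seed=1)
        assert tab.es.iloc[0] == pytest.approx(-1.0)

    def test_score_negation_flips_es_sign(self):
        ranks = self._ranks()
        rng = np.random.default_rng(5)
        members = set(rng.choice(ranks.index, 6, replace=False))
        coll = GeneSetCollection(sets={"S": members})
        fwd = netstats.preranked_gsea(ranks, coll, n_perm=10, weight_p=0.0, seed=2)
        rev = netstats.preranked_gsea(
            (-ranks).iloc[::-1], coll, n_perm=10, weight_p=0.0, seed=2
        )
        assert fwd.es.iloc[0] == pytest.approx(-rev.es.iloc[0])

    def test_p_respects_plus_one_floor(self):
        ranks = self._ranks()
        coll = GeneSetCollection(sets={"top": {ranks.index[0]}})
        tab = netstats.preranked_gsea(ranks, coll, n_perm=100, seed=0)
        assert tab.p_perm.iloc[0] >= 1 / 101


def _classified_path_graph():
    # D - X - C : disease, other, candidate (plus a second candidate C2 - D)
    g = nx.Graph([("D", "X"), ("X", "C"), ("D", "C2")])
    netstats.set_node_classes(g, {"D"}, {"C", "C2"})
    return g


class TestNodeDiseaseStats:
    def test_hand_counted_path_graph(self):
        g = _classified_path_graph()
        tab = netstats.node_disease_stats(g, n_perm=20, seed=0).set_index("gene")
        assert tab.loc["C", "degree"] == 1
        assert tab.loc["C", "disease_neighbor_count"] == 0
        assert tab.loc["C", "mean_sp_disease"] == 2.0
        assert tab.loc["C2", "disease_neighbor_count"] == 1
        assert tab.loc["C2", "interaction_ratio"] == 1.0

    def test_all_disease_neighbors_give_ratio_one(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, str)
        netstats.set_node_classes(g, {"1", "2", "3", "4"}, {"0"})
        g.add_edge("5", "1")
        netstats.set_node_classes(g, {"1", "2", "3", "4"}, {"0", "5"})
        tab = netstats.node_disease_stats(g, n_perm=20, seed=0).set_index("gene")
        assert tab.loc["0", "interaction_ratio"] == 1.0

    def test_ratio_times_degree_equals_count_exactly(self):
        g = synth.simulate_scale_free_network(80, 2, seed=4)
        dis = synth.plant_disease_genes(g, 15, 0.6, seed=4)
        cands = sorted(set(g.nodes()) - dis)[:20]
        netstats.set_node_classes(g, dis, cands)
        tab = netstats.node_disease_stats(g, n_perm=20, seed=1)
        ok = tab.dropna(subset=["interaction_ratio"])
        np.testing.assert_allclose(
            ok.interaction_ratio * ok.degree, ok.disease_neighbor_count, atol=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_shortest_path_means_match_floyd_warshall(self, seed):
        g = nx.gnp_random_graph(50, 0.08, seed=seed)
        g = nx.relabel_nodes(g, str)
        nodes = sorted(g.nodes())
        dis = set(nodes[:10])
        cand = set(nodes[10:25])
        netstats.set_node_classes(g, dis, cand)
        tab = netstats.node_disease_stats(g, n_perm=5, seed=0).set_index("gene")
        oracle_dis = floyd_warshall_means(g, cand, dis)
        oracle_cand = {
            c: v for c, v in floyd_warshall_means(g, cand, cand).items()
        }
        for c in sorted(cand):
            if tab.loc[c, "degree"] == 0:
                continue
            got = tab.loc[c, "mean_sp_disease"]
            exp = oracle_dis[c]
            if np.isnan(exp):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp)
            got_c = tab.loc[c, "mean_sp_candidate"]
            exp_c = oracle_cand[c]
            if np.isnan(exp_c):
                assert np.isnan(got_c)
            else:
                assert got_c == pytest.approx(exp_c)

    def test_permutation_p_never_zero(self):
        g = synth.simulate_scale_free_network(60, 2, seed=9)
        dis = synth.plant_disease_genes(g, 10, 0.8, seed=9)
        cands = sorted(set(g.nodes()) - dis)[:10]
        netstats.set_node_classes(g, dis, cands)
        tab = netstats.node_disease_stats(g, n_perm=50, seed=2)
        assert (tab.p_ratio_perm.dropna() > 0).all()
        assert (tab.p_shortest_perm.dropna() > 0).all()


class TestSelectKeyGenes:
    def _stats(self, p_ratio, p_short, p_count, pct):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(p_ratio))],
                "p_ratio_perm": p_ratio,
                "p_shortest_perm": p_short,
                "p_count_hyper": p_count,
                "degree_percentile": pct,
            }
        )

    def test_reported_significance_profile_selects_all_rows(self):
        # three rows mirroring published disease-hub profiles: permutation
        # ratio p 0.024/0.041/0.048, shortest-path p 0.01/0.015/0.01,
        # analytic count p 6.09e-4/3.04e-6/8.84e-5, top-decile degrees
        stats = self._stats(
            [0.024, 0.041, 0.048],
            [0.01, 0.015, 0.01],
            [0.000609, 3.04e-6, 8.84e-5],
            [0.99, 0.97, 0.95],
        )
        assert netstats.select_key_genes(stats, alpha=0.05) == ["g0", "g1", "g2"]

    def test_alpha_zero_selects_nothing(self):
        stats = self._stats([0.001], [0.001], [0.001], [1.0])
        assert netstats.select_key_genes(stats, alpha=0) == []

    def test_any_failed_axis_excludes(self):
        stats = self._stats(
            [0.01, 0.2, 0.01, 0.01],
            [0.01, 0.01, 0.2, 0.01],
            [0.01, 0.01, 0.01, 0.01],
            [0.99, 0.99, 0.99, 0.5],
        )
        assert netstats.select_key_genes(stats, alpha=0.05) == ["g0"]


def test_null_network_shortest_ratio_near_one():
    """On class-shuffled labels the shortest-path ratio has no signal."""
    g = synth.simulate_scale_free_network(150, 2, seed=11)
    rng = np.random.default_rng(11)
    means = []
    nodes = sorted(g.nodes())
    for s in range(10):
        perm = rng.permutation(nodes)
        netstats.set_node_classes(g, set(perm[:25]), set(perm[25:45]))
        tab = netstats.node_disease_stats(g, n_perm=5, seed=s)
        means.append(tab.shortest_ratio.dropna().mean())
    assert abs(np.mean(means) - 1.0) < 0.05
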