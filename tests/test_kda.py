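import networkx as nx
import numpy as np
import pandas as pd
import pytest

from helpers import hypergeom_upper_tail

from esnpipe.kda import (
    consensus_edges,
    find_key_drivers,
    key_driver_test,
    load_network,
    neighbor_set_enrichment,
    neighborhood,
    rank_across_networks,
)


def _star(n_leaves=20):
    g = nx.DiGraph(network_id="star")
    g.add_edges_from(("hub", f"leaf{i}") for i in range(n_leaves))
    return g


class TestNeighborhood:
    def test_star_out_neighbors(self):
        g = _star(20)
        nbrs = neighborhood(g, "hub", depth=1, direction="out")
        assert nbrs == {f"leaf{i}" for i in range(20)}

    def test_chain_depths(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert neighborhood(g, "a", depth=2, direction="out") == {"b", "c"}
        assert neighborhood(g, "a", depth=1, direction="out") == {"b"}

    def test_in_direction(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert neighborhood(g, "c", depth=2, direction="in") == {"a", "b"}
        assert neighborhood(g, "c", depth=2, direction="out") == set()

    def test_isolated_node(self):
        g = nx.DiGraph()
        g.add_node("x")
        assert neighborhood(g, "x") == set()

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError, match="zzz"):
            neighborhood(_star(), "zzz")


class TestKeyDriverTest:
    def test_hypergeometric_oracle(self):
        g = nx.DiGraph(network_id="n")
        nodes = [f"g{i}" for i in range(100)]
        g.add_nodes_from(nodes)
        g.add_edges_from(("g0", f"g{i}") for i in range(1, 21))
        superset = [f"g{i}" for i in range(1, 16)] + ["g50", "g51"]
        n_nbrs, hits, p = key_driver_test(g, superset, "g0", direction="out")
        assert (n_nbrs, hits) == (20, 15)
        assert p == pytest.approx(hypergeom_upper_tail(15, 99, 17, 20), rel=1e-9)

    def test_disjoint_superset_p_one(self):
        g = _star(10)
        _, hits, p = key_driver_test(g, ["other1", "other2"], "hub")
        assert hits == 0
        assert p == pytest.approx(1.0)

    def test_saturated_margins_p_one(self):
        g = _star(5)
        superset = list(g.nodes)
        *_, p = key_driver_test(g, superset, "hub")
        assert p == pytest.approx(1.0)

    def test_empty_neighborhood_warns(self):
        g = nx.DiGraph()
        g.add_nodes_from(["a", "b"])
        with pytest.warns(UserWarning):
            assert key_driver_test(g, ["b"], "a") == (0, 0, 1.0)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1e6)),
                                    directed=True)
            g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(n)})
            superset = [f"g{i}" for i in range(n) if rng.uniform() < 0.3]
            cand = f"g{int(rng.integers(n))}"
            nbrs = neighborhood(g, cand)
            if not nbrs:
                continue
            _, hits, p = key_driver_test(g, superset, cand)
            expected = hypergeom_upper_tail(
                hits, n - 1, len(set(superset) - {cand}), len(nbrs))
            assert p == pytest.approx(expected, rel=1e-9)


class TestFindKeyDrivers:
    def _planted(self, seed):
        from esnpipe.synthetic_data import SimConfig, simulate_gene_sets, simulate_network
        cfg = SimConfig(seed=seed, n_genes=400, n_gene_sets=5,
                        set_size_range=(40, 50), planted_driver_ids=("g00000",),
                        network_n_nodes=300, hub_degree=30)
        sets = simulate_gene_sets(cfg)
        graph, _ = simulate_network(cfg, sets["set_0000"])
        return graph, sets["set_0000"]

    def test_planted_hub_detected(self):
        hits = 0
        for seed in range(5):
            graph, superset = self._planted(seed)
            res = find_key_drivers(graph, superset)
            flagged = set(res[res["is_key_driver"]]["gene"])
            hits += "g00000" in flagged
        assert hits >= 4

    def test_null_network_mostly_clean(self):
        rng = np.random.default_rng(0)
        false_calls = 0
        for seed in range(5):
            g = nx.gnp_random_graph(300, 0.01, seed=seed, directed=True)
            g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(300)})
            superset = rng.choice([f"g{i}" for i in range(300)], 30,
                                  replace=False)
            res = find_key_drivers(g, superset)
            false_calls += int(res["is_key_driver"].sum() > 0)
        assert false_calls <= 1

    def test_edge_order_invariance_and_duplicates(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "b")]
        g1 = load_network(pd.DataFrame(edges, columns=["source", "target"]))
        g2 = load_network(pd.DataFrame(edges[::-1], columns=["source", "target"]))
        r1 = find_key_drivers(g1, ["b", "c"])
        r2 = find_key_drivers(g2, ["b", "c"])
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            find_key_drivers(nx.DiGraph(), ["a"])


class TestRankAcrossNetworks:
    def _result(self, gene, network, p, is_kd=True):
        return pd.DataFrame([{
            "gene": gene, "network": network, "n_neighbors": 10,
            "n_hits": 5, "p": p, "is_key_driver": is_kd}])

    def test_two_network_arithmetic(self):
        res = [self._result("G", "n1", 1e-4), self._result("G", "n2", 1e-6)]
        out = rank_across_networks(res)
        row = out.iloc[0]
        assert row["n_networks"] == 2
        assert row["consistency"] == pytest.approx(1.01)
        assert row["significance"] == pytest.approx(5.0)
        assert row["rank_score"] == pytest.approx(5.05)

    def test_single_network_arithmetic(self):
        out = rank_across_networks([self._result("G", "n1", 1e-8)])
        assert out.iloc[0]["rank_score"] == pytest.approx(0.08)

    def test_replication_beats_single_strong(self):
        res = [self._result("multi", "n1", 1e-4),
               self._result("multi", "n2", 1e-4),
               self._result("solo", "n1", 1e-8)]
        out = rank_across_networks(res)
        assert out.iloc[0]["gene"] == "multi"
        assert out.iloc[0]["rank_score"] == pytest.approx(4.04)

    def test_non_drivers_excluded(self):
        res = [self._result("G", "n1", 1e-4, is_kd=False)]
        assert rank_across_networks(res).empty

    def test_network_order_invariance(self):
        res = [self._result("A", "n1", 1e-4), self._result("B", "n2", 1e-5),
               self._result("A", "n2", 1e-3)]
        out1 = rank_across_networks(res)
        out2 = rank_across_networks(res[::-1])
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            rank_across_networks([])


class TestNeighborSetEnrichment:
    def test_printed_counts_reproduce_fold(self):
        # pool of 547 neighbors, query of 860 genes with 37 in the pool,
        # universe 21880 -> expected 21.5, fold 1.7
        g = nx.DiGraph(network_id="n")
        seeds = [f"seed{i}" for i in range(5)]
        pool = [f"nbr{i}" for i in range(547)]
        for i, nbr in enumerate(pool):
            g.add_edge(seeds[i % 5], nbr)
        query = pool[:37] + [f"out{i}" for i in range(823)]
        res = neighbor_set_enrichment([g], seeds, query, universe_size=21880,
                                      depth=2)
        assert res.n_neighbors == 547
        assert res.observed == 37
        assert res.expected == pytest.approx(21.5)
        assert round(res.fold, 1) == 1.7
        assert res.p < 0.01

    def test_disjoint_query(self):
        g = _star(10)
        res = neighbor_set_enrichment([g], ["hub"], ["elsewhere"], 1000)
        assert res.fold == 0.0
        assert res.p == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        g = nx.DiGraph(network_id="n")
        pool = [f"n{i}" for i in range(50)]
        g.add_edges_from(("s", x) for x in pool)
        query = pool[:12] + [f"q{i}" for i in range(88)]
        res = neighbor_set_enrichment([g], ["s"], query, universe_size=1000,
                                      depth=2)
        assert res.observed == 12
        assert res.p == pytest.approx(hypergeom_upper_tail(12, 1000, 100, 50),
                                      rel=1e-9)

    def test_min_networks_filter(self):
        g1 = nx.DiGraph([("s", "a"), ("s", "b")])
        g2 = nx.DiGraph([("s", "b"), ("s", "c")])
        res_any = neighbor_set_enrichment([g1, g2], ["s"], ["a", "b", "c"], 100,
                                          min_networks=1)
        res_both = neighbor_set_enrichment([g1, g2], ["s"], ["a", "b", "c"], 100,
                                           min_networks=2)
        assert res_any.n_neighbors == 3
        assert res_both.n_neighbors == 1

    def test_missing_seeds_raise(self):
        with pytest.raises(ValueError):
            neighbor_set_enrichment([_star(3)], ["nope"], ["leaf0"], 100)

    def test_universe_too_small_raises(self):
        with pytest.raises(ValueError):
            neighbor_set_enrichment([_star(10)], ["hub"], ["leaf0"], 5)


class TestInvariantsAndUtilities:
    def test_margin_monotonicity_ordering_preserved(self):
        # adding superset genes outside every neighborhood preserves the
        # p-value ordering among candidates
        g = nx.DiGraph(network_id="n")
        g.add_nodes_from([f"g{i}" for i in range(40)] + [f"x{i}" for i in range(10)])
        g.add_edges_from(("g0", f"g{i}") for i in range(1, 11))
        g.add_edges_from(("g20", f"g{i}") for i in range(21, 31))
        superset = [f"g{i}" for i in range(1, 9)] + ["g25"]
        p_a1 = key_driver_test(g, superset, "g0", direction="out")[2]
        p_b1 = key_driver_test(g, superset, "g20", direction="out")[2]
        bigger = superset + [f"x{i}" for i in range(10)]  # all isolated
        p_a2 = key_driver_test(g, bigger, "g0", direction="out")[2]
        p_b2 = key_driver_test(g, bigger, "g20", direction="out")[2]
        assert (p_a1 < p_b1) == (p_a2 < p_b2)

    def test_load_network_requires_dag(self):
        edges = pd.DataFrame([("a", "b"), ("b", "a")], columns=["source", "target"])
        with pytest.raises(ValueError, match="acyclic"):
            load_network(edges, require_dag=True)

    def test_load_network_drops_self_loops(self):
        edges = pd.DataFrame([("a", "a"), ("a", "b")], columns=["source", "target"])
        g = load_network(edges)
        assert set(g.edges) == {("a", "b")}

    def test_consensus_edges(self):
        g1 = nx.DiGraph([("a", "b"), ("b", "c")])
        g2 = nx.DiGraph([("a", "b")])
        g3 = nx.DiGraph([("a", "b"), ("c", "d")])
        # >30% of 3 networks means >=1, so the default keeps every edge
        assert consensus_edges([g1, g2, g3]) == {
            ("a", "b"), ("b", "c"), ("c", "d")}
        assert consensus_edges([g1, g2, g3], min_count=2) == {("a", "b")}
        assert consensus_edges([g1, g2, g3], min_fraction=0.5) == {("a", "b")}
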