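"""Communities, role scores, centralities and hub rules vs brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from fosnet.topology import (
    MEASURES,
    centralities,
    classify_roles,
    detect_communities,
    exhaustive_modularity_partition,
    identify_hubs,
    participation_coefficient,
    stable_hubs,
    wc_zscore,
)

from conftest import adjacency_dict, net_from_graph, random_weighted_graph


def edge_weights(g: nx.Graph) -> dict:
    return {(u, v): d["weight"] for u, v, d in g.edges(data=True)}


class TestCommunities:
    def test_single_community_has_zero_modularity(self):
        g = random_weighted_graph(np.random.default_rng(0), 8)
        net = net_from_graph(g)
        from fosnet.topology import Partition
        import networkx as nx_

        part = Partition({n: 0 for n in g.nodes}, 0.0, "forced", None, "r")
        q = nx_.community.modularity(g, [set(g.nodes)], weight="weight")
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_joined_by_bridge_recovered(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(base, base + 5):
                for j in range(i + 1, base + 5):
                    g.add_edge(i, j, weight=1.0)
        g.add_edge(0, 5, weight=1.0)
        net = net_from_graph(g)
        part = detect_communities(net, weight_scheme="r", seed=0)
        exact = exhaustive_modularity_partition(net, weight_scheme="r")
        assert part.q == pytest.approx(exact.q, abs=1e-9)
        comms = {frozenset(c) for c in part.communities}
        assert comms == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_empty_graph_yields_singletons(self):
        net = net_from_graph(nx.empty_graph(4))
        part = detect_communities(net)
        assert part.q == 0.0
        assert len(part.communities) == 4

    def test_louvain_deterministic_under_seed(self):
        g = random_weighted_graph(np.random.default_rng(3), 20, p_edge=0.3)
        net = net_from_graph(g)
        a = detect_communities(net, seed=5)
        b = detect_communities(net, seed=5)
        assert a.membership == b.membership and a.q == b.q

    def test_leading_eigenvector_covers_all_nodes(self):
        g = random_weighted_graph(np.random.default_rng(4), 15, p_edge=0.3)
        net = net_from_graph(g)
        part = detect_communities(net, algorithm="leading_eigenvector")
        assert set(part.membership) == set(g.nodes)
        assert part.q >= -1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_louvain_matches_exhaustive_on_small_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_weighted_graph(rng, int(rng.integers(5, 9)), p_edge=0.45)
        if g.number_of_edges() == 0:
            return
        net = net_from_graph(g)
        heur = detect_communities(net, weight_scheme="r", seed=0, n_restarts=16)
        exact_q, _ = oracle.best_modularity_partition(edge_weights(g), list(g.nodes))
        assert heur.q == pytest.approx(exact_q, abs=1e-9)

    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(9)
        g = random_weighted_graph(rng, 7, p_edge=0.5)
        net = net_from_graph(g)
        mine = exhaustive_modularity_partition(net, weight_scheme="r")
        ref_q, _ = oracle.best_modularity_partition(edge_weights(g), [n for n, d in g.degree() if d > 0])
        assert mine.q == pytest.approx(ref_q, abs=1e-9)


class TestRoleScores:
    def _net_and_partition(self, seed=0, n=10):
        g = random_weighted_graph(np.random.default_rng(seed), n, p_edge=0.45)
        net = net_from_graph(g)
        part = detect_communities(net, weight_scheme="r", seed=0)
        return net, part

    def test_wc_zscore_zero_when_degrees_equal(self):
        g = nx.cycle_graph(6)
        net = net_from_graph(g)
        from fosnet.topology import Partition

        part = Partition({n: 0 for n in g.nodes}, 0.0, "forced", None, "r")
        z = wc_zscore(net, part)
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-12)

    def test_wc_zscore_hand_computed_star_community(self):
        # community {a,b,c,d}: within-degrees 3,1,1,1 -> z(a) = 1.732 (population sd)
        g = nx.star_graph(["a", "b", "c", "d"])
        net = net_from_graph(g)
        from fosnet.topology import Partition

        part = Partition({n: 0 for n in g.nodes}, 0.0, "forced", None, "r")
        z = wc_zscore(net, part)
        assert z["a"] == pytest.approx(math.sqrt(3), abs=1e-9)

    def test_wc_zscore_local_to_community(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (3, 4), (4, 5)])
        net = net_from_graph(g)
        from fosnet.topology import Partition

        part = Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}, 0.0, "forced", None, "r")
        before = wc_zscore(net, part)[1]
        g2 = g.copy()
        g2.add_edge(3, 5)  # edge inside the *other* community
        net2 = net_from_graph(g2)
        after = wc_zscore(net2, part)[1]
        assert before == pytest.approx(after, abs=1e-12)

    def test_participation_closed_forms(self):
        # degree 4: 2 edges in own community, 1 each in two others
        g = nx.star_graph(["x", "a", "b", "c", "d"])
        from fosnet.topology import Partition

        membership = {"x": 0, "a": 0, "b": 0, "c": 1, "d": 2}
        part = Partition(membership, 0.0, "forced", None, "r")
        net = net_from_graph(g)
        pc_g = participation_coefficient(net, part, variant="guimera")
        pc_s = participation_coefficient(net, part, variant="simple_ratio")
        assert pc_g["x"] == pytest.approx(1 - (0.5**2 + 0.25**2 + 0.25**2))  # 0.625
        assert pc_s["x"] == pytest.approx(0.5)

    def test_participation_all_internal_is_zero(self):
        g = nx.complete_graph(5)
        from fosnet.topology import Partition

        part = Partition({n: 0 for n in g.nodes}, 0.0, "forced", None, "r")
        net = net_from_graph(g)
        for variant in ("guimera", "simple_ratio"):
            pc = participation_coefficient(net, part, variant=variant)
            np.testing.assert_allclose(pc.to_numpy(), 0.0, atol=1e-12)

    def test_participation_equal_spread_over_m_communities(self):
        m = 4
        g = nx.star_graph(["hub"] + [f"l{i}" for i in range(m)])
        from fosnet.topology import Partition

        membership = {"hub": 0, **{f"l{i}": i for i in range(m)}}
        part = Partition(membership, 0.0, "forced", None, "r")
        pc = participation_coefficient(net_from_graph(g), part, variant="guimera")
        assert pc["hub"] == pytest.approx(1 - 1 / m)

    def test_scores_match_oracles_on_random_graphs(self):
        for seed in range(10):
            net, part = self._net_and_partition(seed=seed, n=11)
            adj = adjacency_dict(net.graph)
            z = wc_zscore(net, part)
            z_ref = oracle.wc_zscore_oracle(adj, part.membership)
            for node in adj:
                assert z[node] == pytest.approx(z_ref[node], abs=1e-9)
            for variant in ("guimera", "simple_ratio"):
                pc = participation_coefficient(net, part, variant=variant)
                pc_ref = oracle.participation_oracle(adj, part.membership, variant)
                for node in adj:
                    assert pc[node] == pytest.approx(pc_ref[node], abs=1e-9)


class TestRoleClassification:
    def test_published_connector_and_provincial_scores(self):
        wc = pd.Series({"MD": 0.670, "BMEa": 1.835, "X": 1.6})
        pc = pd.Series({"MD": 0.912, "BMEa": 0.000, "X": 0.9})
        prof = classify_roles(wc, pc)
        assert prof.table.loc["MD", "role"] == "connector"
        assert prof.table.loc["BMEa", "role"] == "provincial"
        assert prof.table.loc["X", "role"] == "neither"  # fails both exclusive rules

    def test_boundary_values_inclusive(self):
        wc = pd.Series({"a": 1.5, "b": 1.5})
        pc = pd.Series({"a": 0.3, "b": 0.8})
        prof = classify_roles(wc, pc)
        assert prof.table.loc["a", "role"] == "provincial"
        assert prof.table.loc["b", "role"] == "connector"


class TestCentralities:
    def test_star_graph_closed_forms(self):
        g = nx.star_graph(["c", "l1", "l2", "l3", "l4"])
        cent = centralities(net_from_graph(g)).table
        assert cent.loc["c", "bet"] == pytest.approx(6.0)
        assert cent.loc["c", "clo"] == pytest.approx(1.0)
        assert cent.loc["l1", "clo"] == pytest.approx(4 / 7)

    def test_regular_graph_has_equal_eigenvector(self):
        g = nx.cycle_graph(8)
        cent = centralities(net_from_graph(g)).table
        np.testing.assert_allclose(cent["evc"].to_numpy(), 1.0, atol=1e-9)

    def test_isolated_nodes_score_zero(self):
        g = nx.empty_graph(3)
        g.add_edge(0, 1)
        cent = centralities(net_from_graph(g)).table
        assert cent.loc[2, ["wdg", "evc", "bet", "clo"]].tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_all_measures_match_oracles_on_random_weighted_graphs(self):
        """Wdg/Evc/Bet/Clo, clustering, path length and efficiencies agree
        with independent brute-force implementations to 1e-9."""
        from fosnet.network import graph_summary

        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            g = random_weighted_graph(rng, n, p_edge=float(rng.uniform(0.2, 0.8)))
            net = net_from_graph(g)
            adj = adjacency_dict(g)
            cent = centralities(net, weight_scheme="r").table
            summ = graph_summary(net)

            wdg_ref = oracle.weighted_degree(edge_weights(g))
            bet_ref = oracle.betweenness(adj)
            clo_ref = oracle.closeness(adj)
            eff_ref = oracle.nodal_efficiency(adj)
            clu_ref = oracle.clustering(adj)
            for node in g.nodes:
                assert cent.loc[node, "wdg"] == pytest.approx(wdg_ref.get(node, 0.0), abs=1e-9)
                assert cent.loc[node, "bet"] == pytest.approx(bet_ref[node], abs=1e-9)
                assert cent.loc[node, "clo"] == pytest.approx(clo_ref[node], abs=1e-9)
                assert summ.nodal_efficiency[node] == pytest.approx(eff_ref[node], abs=1e-9)
                assert summ.clustering[node] == pytest.approx(clu_ref[node], abs=1e-9)
            assert summ.global_efficiency == pytest.approx(oracle.global_efficiency(adj), abs=1e-9)
            apl_ref = oracle.average_path_length(adj)
            if math.isnan(apl_ref):
                assert math.isnan(summ.average_path_length)
            else:
                assert summ.average_path_length == pytest.approx(apl_ref, abs=1e-9)

            # eigenvector: per component against power iteration
            for comp in oracle.components(adj):
                if len(comp) < 2:
                    continue
                A = nx.to_numpy_array(g, nodelist=comp, weight="weight")
                v = oracle.eigenvector_power(A)
                v = v / v.max()
                for node, ref in zip(comp, v):
                    assert cent.loc[node, "evc"] == pytest.approx(ref, abs=1e-8)


class TestHubs:
    def _table(self, values: dict) -> "object":
        from fosnet.topology import CentralityTable

        df = pd.DataFrame(values)
        for m in MEASURES:
            df[f"rank_{m}"] = df[m].rank(ascending=False, method="min").astype(int)
        return CentralityTable(df, "r")

    def test_top_in_all_measures_is_hub(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(8)]
        vals = {m: pd.Series(rng.uniform(size=8), index=nodes) for m in MEASURES}
        for m in MEASURES:
            vals[m]["n0"] = 2.0  # top everywhere
        res = identify_hubs(self._table(vals))
        assert "n0" in res.hubs

    def test_two_measures_not_enough(self):
        nodes = [f"n{i}" for i in range(8)]
        base = pd.Series(np.linspace(1.0, 0.1, 8), index=nodes)
        vals = {m: base.copy() for m in MEASURES}
        vals["bet"]["n7"] = 3.0
        vals["clo"]["n7"] = 3.0  # top quartile (k=2) in exactly 2 measures
        res = identify_hubs(self._table(vals))
        assert "n7" not in res.hubs
        assert "n0" in res.hubs  # ranked 1st or 2nd in all four

    def test_quartile_size_for_49_nodes(self):
        rng = np.random.default_rng(1)
        nodes = [f"r{i:02d}" for i in range(49)]
        vals = {m: pd.Series(rng.permutation(49).astype(float), index=nodes) for m in MEASURES}
        res = identify_hubs(self._table(vals))
        for m in MEASURES:
            assert len(res.top_sets[m]) == 12  # floor(49 * 0.25)

    def test_tie_at_cutoff_expands_with_notice(self):
        nodes = [f"n{i}" for i in range(8)]
        tied = pd.Series([5.0, 4.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0], index=nodes)
        vals = {m: tied.copy() for m in MEASURES}
        with pytest.warns(UserWarning, match="expanded"):
            res = identify_hubs(self._table(vals))
        assert res.top_sets["wdg"] == {"n0", "n1", "n2", "n3"}
        assert res.tie_expansions["wdg"] == 2

    def test_hub_rule_invariant_to_relabeling(self):
        rng = np.random.default_rng(6)
        g = random_weighted_graph(rng, 14, p_edge=0.4)
        net = net_from_graph(g)
        res = identify_hubs(centralities(net))
        mapping = {n: f"Z{n}" for n in g.nodes}
        net2 = net_from_graph(nx.relabel_nodes(g, mapping))
        res2 = identify_hubs(centralities(net2))
        assert {mapping[h] for h in res.hubs} == res2.hubs


class TestStableHubs:
    def test_identities(self):
        assert stable_hubs({"A", "B"}, {"A", "B"}) == {"A", "B"}
        assert stable_hubs({"A"}, {"B"}) == set()
        assert stable_hubs({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            stable_hubs({"A"})
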