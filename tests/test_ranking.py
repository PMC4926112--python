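"""Centrality scoring, path-damage ratios, and target selection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosforest.ranking import (
    RankingError,
    centrality_table,
    damage_table_directed,
    damage_table_undirected,
    path_damage_directed,
    path_damage_undirected,
    select_targets,
)


def brute_force_directed_ratios(edges, receptors, terminals, cutoff=None):
    """Independent oracle: enumerate receptor->terminal simple paths by DFS."""
    adjacency = {}
    nodes = set()
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        nodes |= {u, v}
    paths = []

    def dfs(path, target):
        if cutoff is not None and len(path) - 1 > cutoff:
            return
        if path[-1] == target:
            paths.append(tuple(path))
            return
        for nxt in adjacency.get(path[-1], []):
            if nxt not in path:
                dfs(path + [nxt], target)

    for r in sorted(set(receptors)):
        for t in sorted(set(terminals) - {r}):
            if r in nodes:
                dfs([r], t)
    inter = sorted(nodes - set(receptors) - set(terminals))
    return {
        v: (sum(1 for p in paths if v in p) / len(paths) if paths else float("nan"))
        for v in inter
    }


class TestCentralities:
    def test_star_hub_dominates_degree_and_betweenness(self):
        g = nx.star_graph(4)
        df, top = centrality_table(nx.relabel_nodes(g, str), k=3)
        assert top["degree"][0] == "0"
        assert top["betweenness"][0] == "0"

    def test_cycle_has_uniform_degree_centrality(self):
        g = nx.relabel_nodes(nx.cycle_graph(6), str)
        df, _ = centrality_table(g)
        assert df["degree"].nunique() == 1

    def test_path_graph_betweenness_matches_pair_enumeration(self):
        g = nx.relabel_nodes(nx.path_graph(7), str)
        df, _ = centrality_table(g)
        mid = df[df["node"] == "3"]["betweenness"].iloc[0]
        # brute force: fraction of node pairs whose unique path crosses node 3
        n = 7
        crossing = sum(
            1
            for a, b in itertools.combinations(range(n), 2)
            if a != 3 and b != 3 and a < 3 < b
        )
        assert mid == pytest.approx(crossing / ((n - 1) * (n - 2) / 2))

    def test_empty_network_rejected(self):
        with pytest.raises(RankingError):
            centrality_table(nx.Graph())

    def test_top_k_ties_broken_by_node_id(self):
        g = nx.relabel_nodes(nx.cycle_graph(5), str)
        _, top = centrality_table(g, k=3)
        assert top["degree"] == ["0", "1", "2"]


class TestDirectedDamage:
    def test_chain_bottleneck_ratio_one(self):
        assert path_damage_directed(
            [("r", "a"), ("a", "t")], ["r"], ["t"], "a"
        ) == pytest.approx(1.0)

    def test_diamond_branch_ratio_half(self):
        edges = [("r", "a"), ("a", "t"), ("r", "b"), ("b", "t")]
        assert path_damage_directed(edges, ["r"], ["t"], "a") == pytest.approx(0.5)

    def test_off_path_node_ratio_zero(self):
        edges = [("r", "a"), ("a", "t"), ("r", "x"), ("x", "y")]
        assert path_damage_directed(edges, ["r"], ["t"], "x") == pytest.approx(0.0)

    def test_disconnecting_node_ratio_one(self):
        edges = [("r1", "m"), ("r2", "m"), ("m", "t1"), ("m", "t2")]
        table = damage_table_directed(edges, ["r1", "r2"], ["t1", "t2"])
        assert table[table["node"] == "m"]["damage_ratio"].iloc[0] == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        nodes = [f"v{i}" for i in range(n)]
        edges = []
        for u, v in itertools.permutations(nodes, 2):
            if rng.random() < 0.15:
                edges.append((u, v))
        receptors = list(rng.choice(nodes, 2, replace=False))
        rest = [x for x in nodes if x not in receptors]
        terminals = list(rng.choice(rest, min(3, len(rest)), replace=False))
        cutoff = 8
        expected = brute_force_directed_ratios(edges, receptors, terminals, cutoff)
        table = damage_table_directed(edges, receptors, terminals, max_path_len=cutoff)
        got = dict(zip(table["node"], table["damage_ratio"]))
        for v, exp in expected.items():
            if np.isnan(exp):
                assert v not in got or np.isnan(got[v])
            else:
                assert got[v] == pytest.approx(exp, abs=1e-12)


class TestUndirectedDamage:
    def _graph(self, edges):
        g = nx.Graph()
        for u, v, c in edges:
            g.add_edge(u, v, cost=c)
        return g

    def test_tree_matches_directed_variant(self):
        und = self._graph([("r", "a", 0.1), ("a", "t", 0.1), ("a", "s", 0.1)])
        ratio = path_damage_undirected(und, ["r"], ["t", "s"], "a")
        directed = path_damage_directed(
            [("r", "a"), ("a", "t"), ("a", "s")], ["r"], ["t", "s"], "a"
        )
        assert ratio == pytest.approx(directed) == pytest.approx(1.0)

    def test_equal_cost_diamond_pools_both_branches(self):
        und = self._graph(
            [("r", "a", 0.2), ("a", "t", 0.2), ("r", "b", 0.2), ("b", "t", 0.2)]
        )
        assert path_damage_undirected(und, ["r"], ["t"], "a") == pytest.approx(0.5)

    def test_pendant_node_ratio_zero(self):
        und = self._graph([("r", "a", 0.1), ("a", "t", 0.1), ("a", "p", 0.1)])
        assert path_damage_undirected(und, ["r"], ["t"], "p") == pytest.approx(0.0)

    def test_costlier_detour_found_after_edge_removal(self):
        und = self._graph(
            [("r", "a", 0.1), ("a", "t", 0.1), ("r", "b", 0.4), ("b", "t", 0.4)]
        )
        table = damage_table_undirected(und, ["r"], ["t"])
        ratios = dict(zip(table["node"], table["damage_ratio"]))
        # pool: shortest path via a, plus detour via b after removing each
        # of the two cheap edges (deduplicated) -> a in 1/2, b in 1/2
        assert ratios["a"] == pytest.approx(0.5)
        assert ratios["b"] == pytest.approx(0.5)


class TestTargetSelection:
    def _spec(self, rows):
        return pd.DataFrame(
            [
                {"node": n, "n": int(p * 10), "prob": p, "specificity": 1 - p}
                for n, p in rows
            ]
        )

    def test_single_centrality_listing_suffices(self):
        top = {m: [] for m in ["degree", "betweenness", "eigenvector", "closeness"]}
        top["pagerank"] = ["hit"]
        out = select_targets(top, [], self._spec([("hit", 0.0)]))
        assert list(out["node"]) == ["hit"]
        assert out.iloc[0]["centrality_pagerank"]
        assert out.iloc[0]["n_criteria"] == 1

    def test_damage_flag_withheld_above_probability_threshold(self):
        damage = pd.DataFrame(
            [{"node": "d", "damaged_paths": 9, "total_paths": 10,
              "damage_ratio": 0.9, "variant": "directed-simple-paths"}]
        )
        out = select_targets({}, [damage], self._spec([("d", 0.9)]))
        assert out.empty

    def test_damage_flag_granted_below_probability_threshold(self):
        damage = pd.DataFrame(
            [{"node": "d", "damaged_paths": 9, "total_paths": 10,
              "damage_ratio": 0.9, "variant": "directed-simple-paths"}]
        )
        out = select_targets({}, [damage], self._spec([("d", 0.2)]))
        assert list(out["node"]) == ["d"]

    def test_twenty_node_fixture_matches_hand_union(self):
        rng = np.random.default_rng(5)
        nodes = [f"p{i:02d}" for i in range(20)]
        top = {
            "degree": nodes[0:4],
            "betweenness": nodes[2:6],
            "eigenvector": nodes[4:8],
            "pagerank": nodes[6:10],
            "closeness": nodes[8:12],
        }
        damage = pd.DataFrame(
            [
                {"node": n, "damaged_paths": i, "total_paths": 20,
                 "damage_ratio": i / 20, "variant": "directed-simple-paths"}
                for i, n in enumerate(nodes)
            ]
        )
        spec = self._spec([(n, 0.1 if i % 2 == 0 else 0.9) for i, n in enumerate(nodes)])
        out = select_targets(top, [damage], spec, k=4)
        # hand union: centrality tops p00..p11; damage top-4 by ratio =
        # p19..p16, filtered to even indices (prob 0.1) -> p18, p16
        expected = set(nodes[0:12]) | {"p18", "p16"}
        assert set(out["node"]) == expected

    def test_target_set_monotone_in_k(self):
        top = {
            "degree": [f"p{i}" for i in range(10)],
            "betweenness": [f"q{i}" for i in range(10)],
        }
        small = select_targets(top, [], None, k=3)
        large = select_targets(top, [], None, k=7)
        assert set(small["node"]) <= set(large["node"])
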