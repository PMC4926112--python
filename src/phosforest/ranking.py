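"""Target prioritization: five centralities, two path-damage ratios, selection.

Candidate targets are ranked on the merged solution network by classical
centrality measures (degree, betweenness, eigenvector, pagerank, closeness)
and by how much receptor-to-terminal signal flow a node carries: the path
damage ratio is the fraction of receptor→terminal paths destroyed when the
node is removed.  The directed variant enumerates simple paths along the
forest's edge orientations; the undirected variant pools, per receptor-
terminal pair, the cost-weighted shortest path plus the alternatives obtained
by deleting each of its edges in turn.  The final target list is the union of
the per-measure top-k sets, with damage-based entries additionally filtered by
the randomization probability (< 0.5 by default).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

CENTRALITY_MEASURES = ("degree", "betweenness", "eigenvector", "pagerank", "closeness")


class RankingError(ValueError):
    pass


def _top_k(scores: Mapping[str, float], k: int) -> List[str]:
    """Top-k node ids by score descending, ties broken by node id ascending."""
    return [
        n for n, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    ]


def centrality_table(
    network: nx.Graph, k: int = 50
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Five classical centralities on the (undirected) merged network.

    Returns the per-node table and the per-measure top-k lists with
    deterministic tie-breaking.  Disconnected networks are accepted.
    """
    if network.number_of_nodes() == 0:
        raise RankingError("cannot rank an empty network")
    g = nx.Graph(network)
    values = {
        "degree": nx.degree_centrality(g),
        "betweenness": nx.betweenness_centrality(g),
        "pagerank": nx.pagerank(g, weight=None),
        "closeness": nx.closeness_centrality(g),
    }
    if g.number_of_edges() == 0:
        values["eigenvector"] = {n: 0.0 for n in g.nodes}
    else:
        values["eigenvector"] = nx.eigenvector_centrality_numpy(g)
    df = pd.DataFrame(
        {
            "node": sorted(g.nodes),
            **{
                m: [abs(values[m][n]) for n in sorted(g.nodes)]
                for m in CENTRALITY_MEASURES
            },
        }
    )
    top = {m: _top_k({n: abs(values[m][n]) for n in g.nodes}, k) for m in CENTRALITY_MEASURES}
    return df, top


# ---------------------------------------------------------------------------
# path damage
# ---------------------------------------------------------------------------


def _directed_paths(
    oriented: nx.DiGraph,
    receptors: Iterable[str],
    terminals: Iterable[str],
    cutoff: Optional[int],
) -> List[Tuple[str, ...]]:
    paths = []
    terminals = {t for t in terminals if t in oriented}
    for r in sorted(set(receptors)):
        if r not in oriented:
            continue
        for t in sorted(terminals - {r}):
            for p in nx.all_simple_paths(oriented, r, t, cutoff=cutoff):
                paths.append(tuple(p))
    return paths


def damage_table_directed(
    network_edges: Iterable[Tuple[str, str]],
    receptors: Iterable[str],
    terminals: Iterable[str],
    max_path_len: Optional[int] = 10,
) -> pd.DataFrame:
    """Damage ratio of every intermediate node under directed simple paths.

    ``network_edges`` are (source, target) pairs oriented away from receptor
    roots.  All receptor→terminal simple paths up to ``max_path_len`` edges are
    enumerated; a node's ratio is the fraction of paths that traverse it.
    Receptors and terminals themselves are not removal candidates.
    """
    dg = nx.DiGraph()
    dg.add_edges_from(network_edges)
    paths = _directed_paths(dg, receptors, terminals, max_path_len)
    return _damage_from_paths(paths, dg.nodes, receptors, terminals, "directed-simple-paths")


def path_damage_directed(
    network_edges: Iterable[Tuple[str, str]],
    receptors: Iterable[str],
    terminals: Iterable[str],
    node: str,
    max_path_len: Optional[int] = 10,
) -> float:
    """Directed damage ratio for one intermediate node (NaN if no paths)."""
    df = damage_table_directed(network_edges, receptors, terminals, max_path_len)
    sel = df[df["node"] == node]
    if sel.empty:
        return float("nan")
    return float(sel["damage_ratio"].iloc[0])


def _undirected_path_pool(
    g: nx.Graph,
    receptors: Iterable[str],
    terminals: Iterable[str],
    weight: str = "cost",
) -> List[Tuple[str, ...]]:
    """Per pair: the shortest path plus single-edge-deletion alternatives."""
    pool: List[Tuple[str, ...]] = []
    terminals = {t for t in terminals if t in g}
    use_weight = weight if all(
        weight in d for _, _, d in g.edges(data=True)
    ) and g.number_of_edges() > 0 else None
    for r in sorted(set(receptors)):
        if r not in g:
            continue
        for t in sorted(terminals - {r}):
            try:
                sp = nx.shortest_path(g, r, t, weight=use_weight)
            except nx.NetworkXNoPath:
                continue
            seen = {tuple(sp)}
            pool.append(tuple(sp))
            for u, v in zip(sp, sp[1:]):
                data = g[u][v]
                g.remove_edge(u, v)
                try:
                    alt = tuple(nx.shortest_path(g, r, t, weight=use_weight))
                    if alt not in seen:
                        seen.add(alt)
                        pool.append(alt)
                except nx.NetworkXNoPath:
                    pass
                finally:
                    g.add_edge(u, v, **data)
    return pool


def damage_table_undirected(
    network: nx.Graph,
    receptors: Iterable[str],
    terminals: Iterable[str],
    weight: str = "cost",
) -> pd.DataFrame:
    """Damage ratio under cost-weighted shortest paths with edge-removal
    alternatives (undirected variant)."""
    g = nx.Graph(network)
    pool = _undirected_path_pool(g, receptors, terminals, weight)
    return _damage_from_paths(pool, g.nodes, receptors, terminals, "undirected-shortest-paths")


def path_damage_undirected(
    network: nx.Graph,
    receptors: Iterable[str],
    terminals: Iterable[str],
    node: str,
    weight: str = "cost",
) -> float:
    """Undirected damage ratio for one intermediate node (NaN if no paths)."""
    df = damage_table_undirected(network, receptors, terminals, weight)
    sel = df[df["node"] == node]
    if sel.empty:
        return float("nan")
    return float(sel["damage_ratio"].iloc[0])


def _damage_from_paths(paths, nodes, receptors, terminals, variant) -> pd.DataFrame:
    receptors, terminals = set(receptors), set(terminals)
    total = len(paths)
    intermediates = sorted(set(nodes) - receptors - terminals)
    rows = []
    for v in intermediates:
        damaged = sum(1 for p in paths if v in p)
        rows.append(
            {
                "node": v,
                "damaged_paths": damaged,
                "total_paths": total,
                "damage_ratio": damaged / total if total else float("nan"),
                "variant": variant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["node", "damaged_paths", "total_paths", "damage_ratio", "variant"],
    )


# ---------------------------------------------------------------------------
# target selection
# ---------------------------------------------------------------------------


def select_targets(
    centrality_top: Mapping[str, Sequence[str]],
    damage_tables: Sequence[pd.DataFrame],
    specificity: Optional[pd.DataFrame] = None,
    k: int = 50,
    prob_threshold: float = 0.5,
) -> pd.DataFrame:
    """Union of per-measure top-k sets; damage criteria filtered by randomness.

    A protein enters the target list if it is in the top-k of at least one
    centrality, or in the top-k by damage ratio of a variant *and* has
    randomization probability below ``prob_threshold``.  Each target carries a
    boolean flag per criterion, its specificity, and a rank (by number of
    satisfied criteria, ties by node id).
    """
    prob = {}
    spec = {}
    if specificity is not None:
        prob = dict(zip(specificity["node"], specificity["prob"]))
        spec = dict(zip(specificity["node"], specificity["specificity"]))

    flags: Dict[str, Dict[str, bool]] = {}
    criteria: List[str] = []
    for measure, top in centrality_top.items():
        crit = f"centrality_{measure}"
        criteria.append(crit)
        for node in list(top)[:k]:
            flags.setdefault(node, {})[crit] = True
    for table in damage_tables:
        variant = table["variant"].iloc[0] if len(table) else "damage"
        crit = f"damage_{variant}"
        criteria.append(crit)
        ranked = table.dropna(subset=["damage_ratio"]).sort_values(
            ["damage_ratio", "node"], ascending=[False, True]
        )
        for node in ranked["node"].head(k):
            if prob.get(node, 0.0) < prob_threshold:
                flags.setdefault(node, {})[crit] = True

    rows = []
    for node, f in flags.items():
        if not any(f.values()):
            continue
        row = {"node": node}
        for crit in criteria:
            row[crit] = bool(f.get(crit, False))
        row["n_criteria"] = sum(row[c] for c in criteria)
        row["specificity"] = float(spec.get(node, float("nan")))
        rows.append(row)
    rows.sort(key=lambda r: (-r["n_criteria"], r["node"]))
    df = pd.DataFrame(rows, columns=["node", *criteria, "n_criteria", "specificity"])
    df["rank"] = range(1, len(df) + 1)
    return df
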