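"""Edge restoration and Girvan–Newman edge-betweenness clustering.

Before clustering, all interactome edges between solution nodes are restored
(the solver keeps only the cheapest connections, so the merged network is
sparser than the underlying biology).  Communities are then found divisively:
the edge with the highest betweenness is removed repeatedly, and the partition
with maximum modularity along the resulting dendrogram is returned (or the
first partition with at least k components, if requested).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import networkx as nx

from .interactome import Interactome
from .perturb import MergedNetwork


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class Clustering:
    """Disjoint, exhaustive partition of the network's nodes."""

    clusters: Tuple[frozenset, ...]
    modularity: float

    def membership(self) -> dict:
        return {n: i for i, c in enumerate(self.clusters) for n in c}

    def __len__(self) -> int:
        return len(self.clusters)


def restore_edges(merged: MergedNetwork, net: Interactome) -> nx.Graph:
    """Induced interactome subgraph on the merged network's nodes.

    Every interactome edge whose endpoints are both in the solution is added
    back (a superset of the merged network's own edges).
    """
    g = net.induced_subgraph(merged.nodes)
    for n in g.nodes:
        g.nodes[n]["terminal"] = n in merged.terminals
        g.nodes[n]["root"] = n in merged.roots
    return g


def _most_central_edge(g: nx.Graph, weighted: bool) -> Tuple[str, str]:
    bet = nx.edge_betweenness_centrality(g, weight="cost" if weighted else None)
    # max betweenness, ties broken by sorted edge id for determinism
    return max(bet, key=lambda e: (bet[e], tuple(sorted(e, reverse=True))))


def edge_betweenness_clusters(
    network: nx.Graph,
    stopping: str = "max-modularity",
    k: Optional[int] = None,
    weighted: bool = False,
) -> Clustering:
    """Girvan–Newman divisive clustering with a deterministic tie-break.

    ``stopping="max-modularity"`` (default) returns the partition of maximum
    modularity along the dendrogram; ``stopping="k-clusters"`` returns the
    first partition with at least ``k`` components.  Edge weights are ignored
    unless ``weighted=True`` (then edge costs drive betweenness).
    """
    if network.number_of_nodes() == 0:
        raise ClusteringError("cannot cluster an empty network")
    if stopping not in ("max-modularity", "k-clusters"):
        raise ClusteringError(f"unknown stopping rule {stopping!r}")
    if stopping == "k-clusters" and (k is None or k < 1):
        raise ClusteringError("k-clusters stopping needs k >= 1")

    g = nx.Graph(network)
    base = nx.Graph(network)  # modularity is evaluated on the original edges

    def partition() -> Tuple[frozenset, ...]:
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(g)),
            key=lambda c: sorted(c),
        )
        return tuple(comps)

    def score(p) -> float:
        if base.number_of_edges() == 0:
            return 0.0
        return nx.community.modularity(base, [set(c) for c in p])

    best_p = partition()
    best_q = score(best_p)
    if stopping == "k-clusters" and len(best_p) >= k:
        return Clustering(clusters=best_p, modularity=best_q)

    while g.number_of_edges():
        g.remove_edge(*_most_central_edge(g, weighted))
        p = partition()
        q = score(p)
        if stopping == "k-clusters":
            if len(p) >= k:
                return Clustering(clusters=p, modularity=q)
        elif q > best_q + 1e-12:
            best_p, best_q = p, q
    if stopping == "k-clusters":
        return Clustering(clusters=partition(), modularity=score(partition()))
    return Clustering(clusters=best_p, modularity=best_q)
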