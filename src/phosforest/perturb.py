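"""Systematic in-silico receptor knockouts and solution merging.

A PCSF solution connects each downstream node to exactly one receptor (the
solver never pays for redundant paths), hiding cross-talk between pathways.
Knocking out a receptor — removing it and all its interactions from the
interactome — and re-solving exposes alternative receptors that can root the
same downstream subtree.  The cascade solves the wild type, then every single
knockout of a wild-type root receptor, then every unordered pair of receptors
observed as roots across those solutions; the union of all solution node and
edge sets is the final merged network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .interactome import Interactome, ReceptorSet
from .pcsf import PCSFConfig, SteinerForest, empty_forest, solve


class PerturbError(ValueError):
    pass


@dataclass(frozen=True)
class KnockoutResult:
    """One run of the cascade: which proteins were removed and what was found."""

    knocked_out: frozenset
    forest: SteinerForest
    roots: tuple  # receptors used as tree roots in this solution

    @property
    def label(self) -> str:
        return "wild_type" if not self.knocked_out else "ko:" + "+".join(
            sorted(self.knocked_out)
        )


@dataclass
class MergedNetwork:
    """Union of nodes/edges over all contributing solutions, with provenance.

    ``node_runs``/``edge_runs`` map each element to the labels of the runs it
    appeared in; ``terminals`` are the merged nodes carrying a positive prize
    in the sample's prize map (everything else is a Steiner node);
    ``oriented_edges`` is the union of tree orientations (away from roots).
    """

    nodes: Set[str] = field(default_factory=set)
    edges: Set[Tuple[str, str]] = field(default_factory=set)
    node_runs: Dict[str, List[str]] = field(default_factory=dict)
    edge_runs: Dict[Tuple[str, str], List[str]] = field(default_factory=dict)
    terminals: Set[str] = field(default_factory=set)
    roots: Set[str] = field(default_factory=set)
    oriented_edges: Set[Tuple[str, str]] = field(default_factory=set)

    @property
    def steiner_nodes(self) -> Set[str]:
        return self.nodes - self.terminals

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        for n in g.nodes:
            g.nodes[n]["terminal"] = n in self.terminals
            g.nodes[n]["root"] = n in self.roots
            g.nodes[n]["runs"] = ",".join(self.node_runs.get(n, []))
        return g


def knockout(net: Interactome, proteins) -> Interactome:
    """Remove ``proteins`` and all their interactions from the interactome."""
    return net.knockout(proteins)


def ko_cascade(
    net: Interactome,
    prizes: Dict[str, float],
    receptors: ReceptorSet,
    config: PCSFConfig,
    ko_all_receptors: bool = False,
) -> List[KnockoutResult]:
    """Wild-type solve, single knockouts, then double knockouts.

    Single knockouts target the receptors used as roots in the wild-type
    solution, plus — to closure — any new root receptor that surfaces in a
    single-knockout solution (all receptors with ``ko_all_receptors=True``).
    Double knockouts target every unordered pair of receptors observed as
    roots across the wild-type and single-knockout solutions.  A knockout
    that leaves no profitable network yields an empty-forest result, not an
    error.
    """
    results: List[KnockoutResult] = []

    wt = solve(net, prizes, receptors, config)
    results.append(KnockoutResult(frozenset(), wt, wt.roots))

    if ko_all_receptors:
        queue = list(sorted(receptors.receptors))
    else:
        queue = list(sorted(wt.roots))
    done: Set[str] = set()
    while queue:
        r = queue.pop(0)
        if r in done:
            continue
        done.add(r)
        res = _solve_ko(net, prizes, receptors, config, {r})
        results.append(res)
        for new_root in sorted(res.roots):
            if new_root not in done and new_root not in queue:
                queue.append(new_root)

    observed_roots: Set[str] = set()
    for res in results:
        observed_roots.update(res.roots)
    for pair in itertools.combinations(sorted(observed_roots), 2):
        results.append(_solve_ko(net, prizes, receptors, config, set(pair)))
    return results


def _solve_ko(net, prizes, receptors, config, ko: Set[str]) -> KnockoutResult:
    ko_net = net.knockout(ko)
    remaining = receptors.receptors - ko
    sub_prizes = {p: v for p, v in prizes.items() if p in ko_net.nodes}
    if not remaining:
        forest = empty_forest(sub_prizes, config)
        return KnockoutResult(frozenset(ko), forest, ())
    ko_receptors = ReceptorSet(receptors=frozenset(remaining))
    forest = solve(ko_net, sub_prizes, ko_receptors, config)
    return KnockoutResult(frozenset(ko), forest, forest.roots)


def merge_solutions(
    results: Sequence[KnockoutResult],
    prizes: Optional[Dict[str, float]] = None,
) -> MergedNetwork:
    """Union of node and edge sets over all contributing solutions.

    Provenance records which runs contributed each node/edge; nodes carrying a
    positive prize are labeled terminals, the rest Steiner nodes.
    """
    if not results:
        raise PerturbError("need at least one solution to merge")
    prizes = prizes or {}
    merged = MergedNetwork()
    for res in results:
        label = res.label
        overlap = res.forest.nodes & res.knocked_out
        if overlap:
            raise PerturbError(
                f"knocked-out protein(s) {sorted(overlap)} appear in their own solution"
            )
        for n in res.forest.nodes:
            merged.nodes.add(n)
            merged.node_runs.setdefault(n, []).append(label)
        for e in res.forest.edges:
            merged.edges.add(e)
            merged.edge_runs.setdefault(e, []).append(label)
        merged.roots.update(res.roots)
        merged.oriented_edges.update(res.forest.oriented_edges())
    merged.terminals = {n for n in merged.nodes if prizes.get(n, 0.0) > 0.0}
    return merged
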