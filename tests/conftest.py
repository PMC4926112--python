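"""Shared fixtures: tiny fixture networks, random PCSF instances, and
independent brute-force oracles for the solvers."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from phosforest.interactome import Interactome, ReceptorSet, make_receptor_set
from phosforest.pcsf import ROOT, AugmentedGraph, PCSFConfig


# ---------------------------------------------------------------------------
# random instance generation
# ---------------------------------------------------------------------------


def random_pcsf_instance(
    seed: int,
    n_nodes: int = 8,
    extra_edges: int = 4,
    n_receptors: int = 2,
    depth: int = 5,
    beta_choices=(0.5, 1.0, 2.0),
    omega_choices=(0.001, 0.3, 1.0),
):
    """A connected random scored graph + receptors + prizes + config."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    perm = list(rng.permutation(nodes))
    triples = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        triples.append((perm[i], perm[j], float(rng.uniform(0.2, 1.0))))
    seen = {tuple(sorted((a, b))) for a, b, _ in triples}
    tries = 0
    while len(triples) < n_nodes - 1 + extra_edges and tries < 200:
        tries += 1
        a, b = rng.choice(nodes, 2, replace=False)
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        triples.append((str(a), str(b), float(rng.uniform(0.2, 1.0))))
    net = Interactome.from_edges(triples)
    receptors = make_receptor_set(
        [str(r) for r in rng.choice(sorted(net.nodes), n_receptors, replace=False)],
        net,
    )
    others = sorted(net.nodes - receptors.receptors)
    n_terminals = int(rng.integers(1, min(4, len(others)) + 1))
    prizes = {
        str(t): float(rng.uniform(0.1, 3.0))
        for t in rng.choice(others, n_terminals, replace=False)
    }
    config = PCSFConfig(
        beta=float(rng.choice(beta_choices)),
        omega=float(rng.choice(omega_choices)),
        depth=depth,
        seed=seed,
    )
    return net, receptors, prizes, config


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_objective(aug: AugmentedGraph, prizes, config) -> float:
    """Exhaustive edge-subset enumeration with tree-feasibility filtering.

    Deliberately dumb and structurally unrelated to the package's exact
    solver: iterate all subsets of augmented edges, keep the ones that form a
    depth-feasible tree containing the artificial root, score each.
    """
    edges = [
        (tuple(sorted((u, v))), d["cost"]) for u, v, d in aug.g.edges(data=True)
    ]
    total = sum(prizes.values())
    best = config.beta * total  # empty forest
    m = len(edges)
    for mask in range(1 << m):
        g = nx.Graph()
        g.add_node(ROOT)
        cost = 0.0
        for i in range(m):
            if mask >> i & 1:
                (u, v), c = edges[i]
                g.add_edge(u, v)
                cost += c
        if g.number_of_edges() != g.number_of_nodes() - 1:
            continue
        if not nx.is_connected(g):
            continue
        depths = nx.single_source_shortest_path_length(g, ROOT)
        if any(d > config.depth for d in depths.values()):
            continue
        collected = sum(prizes.get(n, 0.0) for n in g.nodes if n != ROOT)
        best = min(best, config.beta * (total - collected) + cost)
    return best


def brute_force_forest_objective(net: Interactome, receptors, prizes, config) -> float:
    """Forest-side enumeration (no artificial root): all edge subsets of the
    original graph forming forests whose every component holds a receptor
    within depth-1 of all its nodes, plus optional singleton receptor trees."""
    edges = [(tuple(sorted((u, v))), d["cost"]) for u, v, d in net.g.edges(data=True)]
    recs = set(receptors.receptors)
    total = sum(prizes.values())
    best = config.beta * total
    m = len(edges)
    for mask in range(1 << m):
        g = nx.Graph()
        cost = 0.0
        for i in range(m):
            if mask >> i & 1:
                (u, v), c = edges[i]
                g.add_edge(u, v)
                cost += c
        comps = list(nx.connected_components(g))
        if g.number_of_edges() != g.number_of_nodes() - len(comps):
            continue  # cycle somewhere
        feasible = True
        for comp in comps:
            ok = False
            for r in recs & comp:
                lengths = nx.single_source_shortest_path_length(g.subgraph(comp), r)
                if max(lengths.values()) + 1 <= config.depth:
                    ok = True
                    break
            if not ok:
                feasible = False
                break
        if not feasible:
            continue
        kappa = len(comps)
        used = set(g.nodes)
        collected = sum(prizes.get(n, 0.0) for n in used)
        obj = config.beta * (total - collected) + cost + config.omega * kappa
        # singleton receptor trees for prized receptors outside the forest
        for r in recs - used:
            gain = config.beta * prizes.get(r, 0.0) - config.omega
            if gain > 1e-12:
                obj -= gain
        best = min(best, obj)
    return best


@pytest.fixture
def toy_net():
    """5-node scored network used across fixture tests."""
    return Interactome.from_edges(
        [
            ("A", "B", 0.9),
            ("B", "C", 0.6),
            ("C", "D", 0.8),
            ("A", "D", 0.55),
            ("D", "E", 0.7),
        ]
    )
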