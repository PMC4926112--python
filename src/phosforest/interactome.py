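"""Scored protein-protein interactomes: loading, confidence filtering, cost transform.

An interactome here is an undirected graph whose edges carry an interaction
confidence score ``s_e`` in (0, 1] and a derived cost ``c_e = 1 - s_e``, so that
minimizing a sum of edge costs corresponds to preferring high-likelihood
interactions.  Identifiers are opaque, case-sensitive strings; no gene-symbol
mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

logger = logging.getLogger(__name__)

_COST_TOL = 1e-12


class InteractomeError(ValueError):
    """Raised on malformed interactome input."""


def edge_cost(score: float) -> float:
    """Cost of an edge with confidence ``score``: ``c_e = 1 - s_e``.

    The score must lie in (0, 1]; a perfect-confidence edge is free.
    """
    if not (0.0 < score <= 1.0):
        raise InteractomeError(f"edge score must be in (0, 1], got {score!r}")
    return 1.0 - score


@dataclass(frozen=True)
class ReceptorSet:
    """Cell-surface receptors eligible to root trees.

    ``receptors`` is the subset of listed identifiers found in the interactome;
    ``unmatched`` counts listed identifiers that were absent.
    """

    receptors: frozenset
    unmatched: int = 0

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.receptors))

    def __len__(self) -> int:
        return len(self.receptors)

    def __contains__(self, item: object) -> bool:
        return item in self.receptors


class Interactome:
    """Undirected scored interactome wrapping a :class:`networkx.Graph`.

    Invariants: no self-loops, one edge per unordered pair (duplicates collapse
    to the maximum score), and ``cost == 1 - score`` on every edge.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.g = graph if graph is not None else nx.Graph()
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "Interactome":
        """Build from ``(u, v, score)`` triples; duplicates keep the max score."""
        g = nx.Graph()
        skipped = 0
        for u, v, score in edges:
            u, v = str(u), str(v)
            if not (0.0 < float(score) <= 1.0):
                raise InteractomeError(
                    f"edge score must be in (0, 1], got {score!r} for {u}-{v}"
                )
            if u == v:
                skipped += 1
                continue
            score = float(score)
            if g.has_edge(u, v) and g[u][v]["score"] >= score:
                continue
            g.add_edge(u, v, score=score, cost=1.0 - score)
        if skipped:
            logger.warning("skipped %d self-loop edge(s)", skipped)
        net = cls(g)
        net.n_self_loops_skipped = skipped
        return net

    @classmethod
    def load(cls, path, dialect: str = "tsv") -> "Interactome":
        """Read a scored edge table.

        ``tsv``: three whitespace/tab-separated columns (nodeA, nodeB, score).
        ``sif``: scored SIF dialect (nodeA, relation, nodeB, score).
        """
        path = Path(path)
        if dialect not in ("tsv", "sif"):
            raise InteractomeError(f"unknown dialect {dialect!r}")
        triples = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                try:
                    if dialect == "tsv":
                        u, v, raw = parts[0], parts[1], parts[2]
                    else:
                        u, v, raw = parts[0], parts[2], parts[3]
                    score = float(raw)
                except (IndexError, ValueError) as exc:
                    raise InteractomeError(
                        f"{path}:{lineno}: malformed row {line!r}"
                    ) from exc
                if not (0.0 < score <= 1.0):
                    raise InteractomeError(
                        f"{path}:{lineno}: score {score} outside (0, 1]"
                    )
                triples.append((u, v, score))
        return cls.from_edges(triples)

    # -- basic views ---------------------------------------------------------

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.g.nodes)

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def edges(self) -> Iterator[tuple]:
        """Yield ``(u, v, score, cost)`` with u < v for determinism."""
        for u, v, data in sorted(
            self.g.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
        ):
            a, b = sorted((u, v))
            yield a, b, data["score"], data["cost"]

    def score(self, u, v) -> float:
        return self.g[u][v]["score"]

    def cost(self, u, v) -> float:
        return self.g[u][v]["cost"]

    # -- transforms ----------------------------------------------------------

    def filter_confidence(
        self, threshold: float, keep_isolated: bool = False
    ) -> "Interactome":
        """Keep edges with score >= ``threshold`` (inclusive boundary).

        Isolated nodes are dropped by default; ``keep_isolated=True`` retains
        the full node set.
        """
        if not (0.0 <= threshold <= 1.0):
            raise InteractomeError(f"threshold must be in [0, 1], got {threshold}")
        g = nx.Graph()
        if keep_isolated:
            g.add_nodes_from(self.g.nodes)
        for u, v, data in self.g.edges(data=True):
            if data["score"] >= threshold:
                g.add_edge(u, v, **data)
        return Interactome(g)

    def knockout(self, proteins) -> "Interactome":
        """Remove ``proteins`` and every incident edge (in-silico knockout)."""
        proteins = set(proteins)
        missing = proteins - set(self.g.nodes)
        if missing:
            raise InteractomeError(f"unknown protein(s) in knockout: {sorted(missing)}")
        g = self.g.copy()
        g.remove_nodes_from(proteins)
        return Interactome(g)

    def induced_subgraph(self, nodes) -> nx.Graph:
        nodes = set(nodes)
        missing = nodes - set(self.g.nodes)
        if missing:
            raise InteractomeError(f"unknown node(s): {sorted(missing)}")
        return self.g.subgraph(nodes).copy()

    # -- output --------------------------------------------------------------

    def write(self, path, fmt: str = "tsv") -> None:
        """Write as 3-column TSV, scored SIF, or GraphML (score/cost attrs)."""
        path = Path(path)
        if fmt == "tsv":
            with open(path, "w") as fh:
                for u, v, score, _ in self.edges():
                    fh.write(f"{u}\t{v}\t{score:.10g}\n")
        elif fmt == "sif":
            with open(path, "w") as fh:
                for u, v, score, _ in self.edges():
                    fh.write(f"{u}\tpp\t{v}\t{score:.10g}\n")
        elif fmt == "graphml":
            nx.write_graphml(self.g, path)
        else:
            raise InteractomeError(f"unknown output format {fmt!r}")

    # -- internals -----------------------------------------------------------

    def _validate(self) -> None:
        for u, v, data in self.g.edges(data=True):
            if u == v:
                raise InteractomeError(f"self-loop on {u}")
            score = data.get("score")
            if score is None or not (0.0 < score <= 1.0):
                raise InteractomeError(f"edge {u}-{v} lacks a valid score")
            cost = data.setdefault("cost", 1.0 - score)
            if abs(cost - (1.0 - score)) > _COST_TOL:
                raise InteractomeError(
                    f"edge {u}-{v}: cost {cost} != 1 - score ({1.0 - score})"
                )

    def __repr__(self) -> str:
        return f"Interactome({self.g.number_of_nodes()} nodes, {self.n_edges} edges)"


def load_receptors(path, net: Interactome) -> ReceptorSet:
    """Read one identifier per line; intersect with the interactome nodes.

    Raises if no listed receptor exists in the network (no tree could be
    rooted).  The count of unmatched identifiers is kept on the result.
    """
    path = Path(path)
    listed = []
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                listed.append(name)
    present = frozenset(r for r in listed if r in net.nodes)
    unmatched = len(set(listed)) - len(present)
    if not present:
        raise InteractomeError(
            f"{path}: none of the {len(listed)} listed receptors occur in the network"
        )
    if unmatched:
        logger.warning("%d receptor identifier(s) not found in the network", unmatched)
    return ReceptorSet(receptors=present, unmatched=unmatched)


def make_receptor_set(receptors, net: Interactome) -> ReceptorSet:
    """Validate an in-memory receptor collection against the interactome."""
    present = frozenset(r for r in receptors if r in net.nodes)
    if not present:
        raise InteractomeError("receptor set is empty after matching to the network")
    return ReceptorSet(receptors=present, unmatched=len(set(receptors)) - len(present))
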