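"""Synthetic interactomes with planted receptor-rooted pathways.

The generator emulates the structure of a tumor phosphoproteomics study: a
scored background interactome (scale-free by default, with confidence scores
drawn above the usual 0.5 filter threshold, emulating a pre-thresholded
interaction database), a set of cell-surface receptors, and planted signaling
pathways — receptor-rooted trees of high-confidence edges whose leaf proteins
carry phosphosite signal in the simulated multi-channel experiment.  Channel
intensities are normalized to the channel mean, exactly as the prize
assignment expects, so a leaf active in a subset of samples shows a fold
change of ``effect_size`` in those samples (and the implied reciprocal
deviation elsewhere).

Three planted structures support end-to-end evaluation:

* ordinary pathways (receptor → bottleneck → split nodes → leaves) for node
  recovery;
* a designated *bottleneck* on the largest pathway, plus a backup receptor
  wired to it, so single-receptor knockouts re-root the same subtree;
* an optional *phenotype marker*: a Steiner node behind moderate-confidence
  edges whose child leaves are active exactly in the phenotype-positive
  samples, so the marker's inclusion flips with the per-line prize payoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome, ReceptorSet, make_receptor_set


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPathway:
    """A receptor-rooted tree of true-pathway nodes with boosted edge scores."""

    root: str
    bottleneck: str
    splits: tuple
    leaves: tuple
    backup_root: Optional[str] = None
    edges: tuple = ()

    @property
    def nodes(self) -> frozenset:
        extra = {self.backup_root} if self.backup_root else set()
        return frozenset({self.root, self.bottleneck, *self.splits, *self.leaves} | extra)


@dataclass
class SyntheticScenario:
    """A complete generated study: interactome, receptors, truth, phospho data."""

    net: Interactome
    receptors: ReceptorSet
    pathways: List[PlantedPathway]
    seed: int
    phospho: Optional[pd.DataFrame] = None
    samples: List[str] = field(default_factory=list)
    pathway_activity: Dict[int, frozenset] = field(default_factory=dict)
    marker: Optional[str] = None
    marker_leaves: tuple = ()
    phenotype: Optional[tuple] = None  # bool per sample

    @property
    def planted_nodes(self) -> Set[str]:
        out: Set[str] = set()
        for p in self.pathways:
            out |= set(p.nodes)
        return out

    @property
    def planted_steiner_nodes(self) -> Set[str]:
        """Planted nodes that never carry phosphosite signal (interior nodes)."""
        out: Set[str] = set()
        for p in self.pathways:
            out |= {p.bottleneck, *p.splits}
        if self.marker:
            out.add(self.marker)
        return out


# ---------------------------------------------------------------------------
# interactome generation
# ---------------------------------------------------------------------------


def generate_interactome(
    n_nodes: int = 100,
    topology: str = "scale_free",
    score_range: Tuple[float, float] = (0.5, 0.9),
    score_shape: Tuple[float, float] = (2.0, 2.0),
    attachment: int = 2,
    edge_prob: float = 0.05,
    seed: int = 0,
) -> Interactome:
    """Random scored interactome: scale-free (preferential attachment) or
    Erdős–Rényi topology with Beta-distributed scores rescaled into
    ``score_range``."""
    if n_nodes < 10:
        raise SyntheticError("need at least 10 nodes")
    lo, hi = score_range
    if not (0.0 < lo <= hi <= 1.0):
        raise SyntheticError(f"invalid score range {score_range}")
    a, b = score_shape
    if a <= 0 or b <= 0:
        raise SyntheticError(f"invalid Beta shape {score_shape}")
    rng = np.random.default_rng(abs(int(seed)) % (2**31))
    if topology == "scale_free":
        g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng.integers(2**31)))
    elif topology == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31)))
    else:
        raise SyntheticError(f"unknown topology {topology!r}")
    width = max(n_nodes - 1, 1)
    digits = len(str(width))
    mapping = {i: f"P{i:0{digits}d}" for i in g.nodes}
    triples = []
    for u, v in sorted(g.edges):
        s = lo if hi == lo else lo + (hi - lo) * float(rng.beta(a, b))
        triples.append((mapping[u], mapping[v], min(s, 1.0)))
    return Interactome.from_edges(triples)


def choose_receptors(net: Interactome, n_receptors: int, seed: int = 0) -> ReceptorSet:
    """Pick receptors uniformly at random from the interactome nodes."""
    rng = np.random.default_rng(abs(int(seed)) % (2**31))
    nodes = sorted(net.nodes)
    if n_receptors > len(nodes):
        raise SyntheticError("more receptors requested than nodes available")
    chosen = rng.choice(nodes, size=n_receptors, replace=False)
    return make_receptor_set([str(c) for c in chosen], net)


# ---------------------------------------------------------------------------
# pathway planting
# ---------------------------------------------------------------------------


def plant_pathways(
    net: Interactome,
    receptors: ReceptorSet,
    n_pathways: int = 3,
    leaves_per_pathway: int = 3,
    pathway_score: float = 0.97,
    backup_root_score: float = 0.95,
    big_first: bool = True,
    seed: int = 0,
) -> SyntheticScenario:
    """Plant receptor-rooted trees of high-confidence edges.

    Each pathway is ``root → bottleneck → split node(s) → leaves`` (leaf depth
    3 from the receptor), node-disjoint across pathways.  Leaves are recycled
    background proteins; interior nodes (bottleneck, splits) are dedicated
    fresh proteins whose only interactions are the pathway edges, modeling
    pathway-specific adaptors rather than promiscuous hubs.  With
    ``big_first`` the first pathway gets twice the leaves, two split nodes and
    a backup receptor wired to its bottleneck at slightly lower confidence —
    the canonical shared-downstream-pathway situation a receptor knockout
    exposes.
    """
    rng = np.random.default_rng(abs(int(seed)) % (2**31))
    rec_sorted = sorted(receptors.receptors)
    need_recs = n_pathways + (1 if big_first else 0)
    if len(rec_sorted) < need_recs:
        raise SyntheticError(
            f"{need_recs} receptors needed for {n_pathways} pathways, have {len(rec_sorted)}"
        )
    roots = [str(r) for r in rng.choice(rec_sorted, size=need_recs, replace=False)]
    backup = roots.pop() if big_first else None

    free = sorted(net.nodes - receptors.receptors)
    rng.shuffle(free)
    free_iter = iter(free)

    def take(k: int) -> List[str]:
        out = []
        for _ in range(k):
            try:
                out.append(str(next(free_iter)))
            except StopIteration:
                raise SyntheticError("interactome too small for requested pathways")
        return out

    g = net.g.copy()

    def boost(u, v, score):
        if g.has_edge(u, v):
            score = max(score, g[u][v]["score"])
        g.add_edge(u, v, score=score, cost=1.0 - score)

    pathways = []
    for i in range(n_pathways):
        big = big_first and i == 0
        n_leaves = leaves_per_pathway * (2 if big else 1)
        n_splits = 2 if big else 1
        bottleneck = f"PW{i}B"
        splits = [f"PW{i}S{j}" for j in range(n_splits)]
        leaves = take(n_leaves)
        edges = [(roots[i], bottleneck)]
        if big and backup is not None:
            boost(backup, bottleneck, backup_root_score)
        for s in splits:
            edges.append((bottleneck, s))
        for j, leaf in enumerate(leaves):
            edges.append((splits[j % n_splits], leaf))
        for u, v in edges:
            boost(u, v, pathway_score)
        pathways.append(
            PlantedPathway(
                root=roots[i],
                bottleneck=bottleneck,
                splits=tuple(splits),
                leaves=tuple(leaves),
                backup_root=backup if big else None,
                edges=tuple(edges),
            )
        )
    return SyntheticScenario(
        net=Interactome(g), receptors=receptors, pathways=pathways, seed=seed
    )


def add_phenotype_marker(
    scenario: SyntheticScenario,
    n_samples: int,
    positive_lines: Sequence[int],
    marker_edge_score: float = 0.52,
) -> SyntheticScenario:
    """Attach a marker chain to the first pathway's bottleneck.

    The marker is a fresh Steiner node behind a moderate-confidence edge; it
    carries one fresh leaf per phenotype-positive line, each active exactly in
    that line.  The per-leaf prize payoff in positive lines exceeds the chain
    cost, while the reciprocal payoff in negative lines does not, so the
    marker enters the solution exactly in positive lines.
    """
    if not scenario.pathways:
        raise SyntheticError("plant pathways before adding a marker")
    positive = sorted(set(int(i) for i in positive_lines))
    if any(i < 0 or i >= n_samples for i in positive):
        raise SyntheticError("positive line index out of range")
    g = scenario.net.g.copy()
    bottleneck = scenario.pathways[0].bottleneck
    marker = "MARKER"
    leaves = tuple(f"MLEAF{i}" for i in positive)
    g.add_edge(bottleneck, marker, score=marker_edge_score, cost=1 - marker_edge_score)
    for leaf in leaves:
        g.add_edge(marker, leaf, score=marker_edge_score, cost=1 - marker_edge_score)
    scenario.net = Interactome(g)
    scenario.marker = marker
    scenario.marker_leaves = leaves
    scenario.phenotype = tuple(i in positive for i in range(n_samples))
    return scenario


# ---------------------------------------------------------------------------
# phospho simulation
# ---------------------------------------------------------------------------


def simulate_phospho(
    scenario: SyntheticScenario,
    n_samples: int = 8,
    effect_size: float = 4.0,
    noise_sd: float = 0.05,
    background_fraction: float = 0.3,
    max_sites_per_protein: int = 3,
    pathway_activity: Optional[Dict[int, Sequence[int]]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-channel phosphosite intensities for the scenario's proteins.

    Planted leaf proteins receive 1..``max_sites_per_protein`` sites whose
    intensity pattern equals ``effect_size`` in their pathway's active samples
    and the mean-preserving complement elsewhere, so after per-site channel
    normalization the active fold change is exactly ``effect_size`` (up to the
    multiplicative lognormal noise of width ``noise_sd``).  A fraction of
    background proteins receives pure-noise sites.  Marker leaves are active
    exactly in their own phenotype-positive line.
    """
    if effect_size <= 0:
        raise SyntheticError("effect size must be positive")
    if noise_sd < 0:
        raise SyntheticError("noise must be non-negative")
    rng = np.random.default_rng(abs(int(seed)) % (2**31))
    samples = [f"S{i + 1}" for i in range(n_samples)]

    if pathway_activity is None:
        pathway_activity = {i: [0] for i in range(len(scenario.pathways))}
    activity: Dict[str, frozenset] = {}
    for i, p in enumerate(scenario.pathways):
        act = frozenset(int(x) for x in pathway_activity.get(i, []))
        if any(x < 0 or x >= n_samples for x in act):
            raise SyntheticError("active sample index out of range")
        scenario.pathway_activity[i] = act
        for leaf in p.leaves:
            activity[leaf] = act
    for line, leaf in zip(
        [i for i, f in enumerate(scenario.phenotype or []) if f], scenario.marker_leaves
    ):
        activity[leaf] = frozenset({line})

    def pattern(active: frozenset) -> np.ndarray:
        m = np.ones(n_samples)
        if active:
            k = len(active)
            inactive_value = (n_samples - k * effect_size) / (n_samples - k) if n_samples > k else 0.0
            if inactive_value <= 0:
                raise SyntheticError(
                    f"effect {effect_size} in {k}/{n_samples} samples leaves no "
                    "mass for inactive channels; lower the effect or activity"
                )
            m[:] = inactive_value
            m[sorted(active)] = effect_size
        return m

    rows = []

    def emit(protein: str, active: frozenset):
        # marker leaves carry a single site so their prize tracks the planted
        # pattern without the upward bias of a max over noisy replicates
        if protein in scenario.marker_leaves:
            n_sites = 1
        else:
            n_sites = int(rng.integers(1, max_sites_per_protein + 1))
        base = pattern(active)
        for s in range(n_sites):
            noise = rng.lognormal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 1.0
            rows.append(
                {
                    "protein": protein,
                    "site": f"{protein}_Y{s + 1}",
                    **dict(zip(samples, base * noise)),
                }
            )

    for leaf in sorted(activity):
        emit(leaf, activity[leaf])

    background = sorted(
        scenario.net.nodes
        - scenario.planted_nodes
        - set(scenario.receptors.receptors)
        - {scenario.marker, *scenario.marker_leaves}
    )
    n_bg = int(round(background_fraction * len(background)))
    for protein in rng.choice(background, size=min(n_bg, len(background)), replace=False):
        emit(str(protein), frozenset())

    df = pd.DataFrame(rows, columns=["protein", "site", *samples]).set_index(
        ["protein", "site"]
    )
    scenario.phospho = df
    scenario.samples = samples
    return df


# ---------------------------------------------------------------------------
# scenario persistence
# ---------------------------------------------------------------------------


def write_scenario(scenario: SyntheticScenario, out_dir) -> None:
    """Write interactome TSV, receptor list, phospho TSV and ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario.net.write(out / "interactome.tsv", fmt="tsv")
    (out / "receptors.txt").write_text(
        "".join(f"{r}\n" for r in sorted(scenario.receptors.receptors))
    )
    if scenario.phospho is not None:
        scenario.phospho.reset_index().to_csv(
            out / "phospho.tsv", sep="\t", index=False, float_format="%.10g"
        )
    truth = {
        "seed": scenario.seed,
        "pathways": [
            {
                "root": p.root,
                "backup_root": p.backup_root,
                "bottleneck": p.bottleneck,
                "splits": list(p.splits),
                "leaves": list(p.leaves),
            }
            for p in scenario.pathways
        ],
        "pathway_activity": {str(k): sorted(v) for k, v in scenario.pathway_activity.items()},
        "marker": scenario.marker,
        "marker_leaves": list(scenario.marker_leaves),
        "phenotype": list(scenario.phenotype) if scenario.phenotype else None,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
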