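"""Random-terminal null ensembles, node specificity, and phenotype-pattern odds.

Reconstructed networks mix disease-specific proteins with generic hubs that
would appear for almost any terminal set.  To separate the two, the observed
prize values are reassigned to randomly drawn terminal sets of the same size
(N replicates, default 100), each replicate is run through the same knockout
cascade and merge as the real data, and every node is scored by the fraction
of random networks containing it: prob(v) = n/N.  The specificity index
1 - prob(v) is high for nodes rarely recruited by chance.  The same per-line
frequencies give the probability that a node's presence/absence pattern
across samples would match a binary phenotype in random networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .interactome import Interactome, ReceptorSet
from .pcsf import PCSFConfig, ROOT
from .perturb import MergedNetwork, ko_cascade, merge_solutions


class RandomizeError(ValueError):
    pass


@dataclass
class RandomEnsemble:
    """N random prize maps sharing the observed prize-value multiset."""

    prize_maps: List[Dict[str, float]]
    seed: int

    @property
    def n(self) -> int:
        return len(self.prize_maps)


def random_terminal_sets(
    net: Interactome,
    prizes: Dict[str, float],
    n_sets: int = 100,
    seed: int = 0,
    exclude_receptors: Optional[ReceptorSet] = None,
) -> RandomEnsemble:
    """Resample terminal sets of the observed size with the observed prizes.

    Terminals are drawn uniformly without replacement from the interactome
    nodes (optionally excluding receptors); the observed prize multiset is
    randomly permuted onto them.  Replicate k is reproducible from
    (seed, k) alone.
    """
    values = sorted(prizes.values())
    if not values:
        raise RandomizeError("observed prize map is empty")
    eligible = sorted(net.nodes - {ROOT})
    if exclude_receptors is not None:
        eligible = sorted(set(eligible) - set(exclude_receptors.receptors))
    if len(eligible) < len(values):
        raise RandomizeError(
            f"only {len(eligible)} eligible nodes for {len(values)} terminals"
        )
    maps = []
    for k in range(n_sets):
        rng = np.random.default_rng([abs(int(seed)) % (2**31), k])
        chosen = rng.choice(eligible, size=len(values), replace=False)
        perm = rng.permutation(values)
        maps.append({str(node): float(v) for node, v in zip(chosen, perm)})
    return RandomEnsemble(prize_maps=maps, seed=seed)


def solve_ensemble(
    net: Interactome,
    ensemble: RandomEnsemble,
    receptors: ReceptorSet,
    config: PCSFConfig,
    cascade: bool = True,
    progress: Optional[Callable[[int], None]] = None,
) -> List[MergedNetwork]:
    """Run each replicate through the same solve (and knockout cascade/merge)
    procedure as the observed data."""
    merged = []
    for k, pm in enumerate(ensemble.prize_maps):
        if cascade:
            results = ko_cascade(net, pm, receptors, config)
        else:
            from .pcsf import solve as _solve
            from .perturb import KnockoutResult

            forest = _solve(net, pm, receptors, config)
            results = [KnockoutResult(frozenset(), forest, forest.roots)]
        merged.append(merge_solutions(results, pm))
        if progress is not None:
            progress(k)
    return merged


def node_frequency(
    replicate_networks: Sequence[MergedNetwork], universe=None
) -> Dict[str, int]:
    """n(v) = number of replicate networks whose node set contains v."""
    counts: Dict[str, int] = {}
    if universe is not None:
        counts = {str(v): 0 for v in universe}
    for mn in replicate_networks:
        for v in mn.nodes:
            counts[v] = counts.get(v, 0) + 1
    return counts


def specificity_index(freq: Mapping[str, int], n_replicates: int) -> pd.DataFrame:
    """Table of n, prob = n/N, and specificity = 1 - prob per node."""
    if n_replicates < 1:
        raise RandomizeError("need at least one replicate")
    bad = {v: n for v, n in freq.items() if n < 0 or n > n_replicates}
    if bad:
        raise RandomizeError(f"counts outside [0, N]: {bad}")
    rows = [
        {
            "node": v,
            "n": int(n),
            "prob": n / n_replicates,
            "specificity": 1.0 - n / n_replicates,
        }
        for v, n in sorted(freq.items())
    ]
    return pd.DataFrame(rows, columns=["node", "n", "prob", "specificity"])


def phenotype_match_probability(
    per_line_probs: Sequence[Mapping[str, float]],
    pattern: Sequence[bool],
) -> pd.DataFrame:
    """Chance probability of a node tracking a binary phenotype across lines.

    ``per_line_probs[l]`` maps node -> probability of appearing in a random
    network of line l; ``pattern[l]`` is True where the phenotype requires
    presence.  Treating replicate draws across lines as independent,

        P_match(v) = prod_l  prob_l(v)       if pattern[l]
                             1 - prob_l(v)   otherwise.

    Returns one row per node plus the any-node summary
    ``1 - prod_v (1 - P_match(v))`` in ``df.attrs["any_node_probability"]``.
    """
    if len(per_line_probs) != len(pattern):
        raise RandomizeError(
            f"{len(per_line_probs)} probability tables but pattern of length {len(pattern)}"
        )
    nodes = sorted(set().union(*[set(t) for t in per_line_probs]))
    rows = []
    for v in nodes:
        p = 1.0
        for table, present in zip(per_line_probs, pattern):
            prob = float(table.get(v, 0.0))
            if not (0.0 <= prob <= 1.0):
                raise RandomizeError(f"probability {prob} for {v} outside [0, 1]")
            p *= prob if present else 1.0 - prob
        rows.append({"node": v, "match_probability": p})
    df = pd.DataFrame(rows, columns=["node", "match_probability"])
    none_match = float(np.prod([1.0 - r["match_probability"] for r in rows])) if rows else 1.0
    df.attrs["any_node_probability"] = 1.0 - none_match
    return df


def rank_phenotype_markers(
    observed_presence: Sequence[Mapping[str, bool]],
    per_line_probs: Sequence[Mapping[str, float]],
    pattern: Sequence[bool],
    candidates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Rank candidate marker nodes by phenotype agreement, then rarity.

    A node's observed pattern is its presence/absence across the per-line
    networks.  Nodes are sorted by the number of lines where the observed
    pattern agrees with the phenotype (descending), breaking ties by the
    chance probability of matching the phenotype in random networks
    (ascending) and then by node id.
    """
    if len(observed_presence) != len(pattern):
        raise RandomizeError("presence tables and pattern length differ")
    match = phenotype_match_probability(per_line_probs, pattern)
    chance = dict(zip(match["node"], match["match_probability"]))
    if candidates is None:
        candidates = sorted(set().union(*[set(t) for t in observed_presence]))
    rows = []
    for v in candidates:
        agree = sum(
            1
            for table, present in zip(observed_presence, pattern)
            if bool(table.get(v, False)) == bool(present)
        )
        rows.append(
            {
                "node": v,
                "agreement": agree,
                "chance_probability": float(chance.get(v, 0.0)),
            }
        )
    rows.sort(key=lambda r: (-r["agreement"], r["chance_probability"], r["node"]))
    df = pd.DataFrame(rows, columns=["node", "agreement", "chance_probability"])
    df["rank"] = range(1, len(df) + 1)
    return df
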