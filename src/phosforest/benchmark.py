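"""End-to-end benchmark harnesses on planted synthetic scenarios.

These drive the full pipeline — prize assignment, receptor-rooted PCSF solve,
knockout cascade, merge, randomization, ranking — against scenarios with
known ground truth, and report recovery/ranking metrics.  They are used both
by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .interactome import Interactome
from .pcsf import PCSFConfig
from .perturb import MergedNetwork, ko_cascade, merge_solutions
from .prizes import prizes_from_phospho
from .randomize import (
    node_frequency,
    random_terminal_sets,
    rank_phenotype_markers,
    solve_ensemble,
    specificity_index,
)
from .ranking import damage_table_directed
from .synthetic import (
    SyntheticScenario,
    add_phenotype_marker,
    choose_receptors,
    generate_interactome,
    plant_pathways,
    simulate_phospho,
)

#: Solver defaults for benchmark pipelines; beta/omega/depth are the standard
#: reconstruction parameters, restarts trimmed for throughput.
BENCH_CONFIG = PCSFConfig(beta=2.0, omega=0.001, depth=10, restarts=8)


def recovery_scenario(
    seed: int,
    n_nodes: int = 90,
    n_receptors: int = 8,
    n_pathways: int = 3,
    effect_size: float = 4.0,
    noise_sd: float = 0.05,
    n_samples: int = 8,
    background_fraction: float = 0.25,
) -> SyntheticScenario:
    """Planted-pathway scenario with all pathways active in the first sample."""
    net = generate_interactome(n_nodes=n_nodes, seed=seed)
    receptors = choose_receptors(net, n_receptors, seed=seed + 1)
    scenario = plant_pathways(net, receptors, n_pathways=n_pathways, seed=seed + 2)
    simulate_phospho(
        scenario,
        n_samples=n_samples,
        effect_size=effect_size,
        noise_sd=noise_sd,
        background_fraction=background_fraction,
        pathway_activity={i: [0] for i in range(n_pathways)},
        seed=seed + 3,
    )
    return scenario


def solve_scenario_sample(
    scenario: SyntheticScenario,
    sample: str,
    config: Optional[PCSFConfig] = None,
) -> Tuple[MergedNetwork, Dict[str, float]]:
    """Prizes for one sample, knockout cascade, merge."""
    config = config or BENCH_CONFIG
    prizes = prizes_from_phospho(scenario.phospho, sample)
    results = ko_cascade(scenario.net, prizes, scenario.receptors, config)
    return merge_solutions(results, prizes), prizes


#: Simple-path cap for damage ranking on the benchmark: planted pathways are
#: 3 edges deep, so receptor-to-leaf routes of interest have <= 4 edges; the
#: cap keeps long braided knockout-reroute paths from swamping the counts.
DAMAGE_PATH_CAP = 4


def recovery_benchmark(
    scenario: SyntheticScenario, config: Optional[PCSFConfig] = None
) -> Dict[str, object]:
    """One cascade solve scored two ways: planted-node F1 and bottleneck rank.

    F1 compares the merged network's nodes with the planted pathway nodes;
    the rank is the planted bottleneck's position among intermediate nodes
    ordered by directed path-damage ratio (1 = top).
    """
    merged, _ = solve_scenario_sample(scenario, scenario.samples[0], config)
    truth = scenario.planted_nodes
    predicted = set(merged.nodes)
    tp = len(truth & predicted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0

    table = damage_table_directed(
        merged.oriented_edges,
        receptors=merged.roots,
        terminals=merged.terminals,
        max_path_len=DAMAGE_PATH_CAP,
    )
    ranked = table.dropna(subset=["damage_ratio"]).sort_values(
        ["damage_ratio", "node"], ascending=[False, True]
    )
    nodes = list(ranked["node"])
    bottleneck = scenario.pathways[0].bottleneck
    rank = nodes.index(bottleneck) + 1 if bottleneck in nodes else len(nodes) + 1
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "bottleneck_rank": rank,
        "damage_table": ranked,
        "merged": merged,
    }


def specificity_scenario(
    seed: int,
    n_nodes: int = 250,
    n_receptors: int = 8,
    n_pathways: int = 2,
) -> SyntheticScenario:
    """Sparse-terminal scenario for the specificity property.

    The interactome is large relative to the terminal count, so random
    terminal draws rarely touch the planted pathways, and the confidence gap
    between planted (0.8) and background (0.5–0.75) edges is kept moderate so
    the pathways are not free thoroughfares for null solutions.  Planted
    Steiner nodes should then be rare in null networks while hubs stay common.
    """
    net = generate_interactome(
        n_nodes=n_nodes, score_range=(0.5, 0.75), seed=seed
    )
    receptors = choose_receptors(net, n_receptors, seed=seed + 1)
    scenario = plant_pathways(
        net,
        receptors,
        n_pathways=n_pathways,
        leaves_per_pathway=2,
        pathway_score=0.8,
        backup_root_score=0.78,
        seed=seed + 2,
    )
    simulate_phospho(
        scenario,
        n_samples=8,
        effect_size=4.0,
        noise_sd=0.05,
        background_fraction=0.08,
        pathway_activity={i: [0] for i in range(n_pathways)},
        seed=seed + 3,
    )
    return scenario


def hub_vs_planted_specificity(
    scenario: SyntheticScenario,
    n_random: int = 20,
    seed: int = 0,
    config: Optional[PCSFConfig] = None,
) -> Dict[str, float]:
    """Mean specificity of planted Steiner nodes vs top-decile-degree hubs."""
    config = config or BENCH_CONFIG
    prizes = prizes_from_phospho(scenario.phospho, scenario.samples[0])
    ensemble = random_terminal_sets(scenario.net, prizes, n_random, seed=seed)
    replicates = solve_ensemble(scenario.net, ensemble, scenario.receptors, config)
    freq = node_frequency(replicates, universe=scenario.net.nodes)
    spec = specificity_index(freq, n_random)
    spec_map = dict(zip(spec["node"], spec["specificity"]))

    degrees = dict(scenario.net.g.degree())
    cutoff = np.quantile(sorted(degrees.values()), 0.9)
    hubs = [n for n, d in degrees.items() if d >= cutoff]
    planted = sorted(scenario.planted_steiner_nodes - set(hubs))
    return {
        "hub_mean_specificity": float(np.mean([spec_map[h] for h in hubs])),
        "planted_mean_specificity": float(np.mean([spec_map[p] for p in planted])),
    }


# ---------------------------------------------------------------------------
# phenotype-marker benchmark
# ---------------------------------------------------------------------------


def phenotype_scenario(
    seed: int,
    n_nodes: int = 60,
    n_receptors: int = 5,
    n_samples: int = 8,
    positive_lines: Sequence[int] = (0, 1),
    effect_size: float = 2.0,
    noise_sd: float = 0.05,
) -> SyntheticScenario:
    """Marker scenario: base pathways active off-pattern, marker on-pattern.

    Base pathway activities are pairwise at Hamming distance >= 2 from the
    phenotype so no planted competitor can match the marker's pattern.
    """
    net = generate_interactome(n_nodes=n_nodes, seed=seed)
    receptors = choose_receptors(net, n_receptors, seed=seed + 1)
    scenario = plant_pathways(net, receptors, n_pathways=3, seed=seed + 2)
    scenario = add_phenotype_marker(scenario, n_samples, positive_lines)
    negatives = [i for i in range(n_samples) if i not in set(positive_lines)]
    activity = {
        i: negatives[2 * i : 2 * i + 2] if len(negatives) >= 2 * i + 2 else negatives[:1]
        for i in range(3)
    }
    simulate_phospho(
        scenario,
        n_samples=n_samples,
        effect_size=effect_size,
        noise_sd=noise_sd,
        background_fraction=0.2,
        pathway_activity=activity,
        seed=seed + 3,
    )
    return scenario


def phenotype_marker_rank(
    scenario: SyntheticScenario,
    n_random: int = 15,
    seed: int = 0,
    config: Optional[PCSFConfig] = None,
) -> Tuple[int, pd.DataFrame]:
    """Solve every line, build per-line null ensembles, rank marker candidates.

    Returns the planted marker's rank (1 = best) among Steiner-node candidates
    and the full ranking table.  Null-ensemble replicates run the same cascade
    procedure with a lighter restart budget for throughput.
    """
    config = config or replace(BENCH_CONFIG, restarts=4)
    replicate_config = replace(config, restarts=min(config.restarts, 2))
    presence, probs, candidates = [], [], set()
    for line, sample in enumerate(scenario.samples):
        merged, prizes = solve_scenario_sample(scenario, sample, config)
        presence.append({n: True for n in merged.nodes})
        candidates |= set(merged.steiner_nodes)
        ensemble = random_terminal_sets(
            scenario.net, prizes, n_random, seed=seed * 1009 + line
        )
        replicates = solve_ensemble(
            scenario.net, ensemble, scenario.receptors, replicate_config
        )
        freq = node_frequency(replicates)
        probs.append({n: c / n_random for n, c in freq.items()})
    ranking = rank_phenotype_markers(
        presence, probs, scenario.phenotype, sorted(candidates)
    )
    row = ranking[ranking["node"] == scenario.marker]
    rank = int(row["rank"].iloc[0]) if len(row) else len(ranking) + 1
    return rank, ranking
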