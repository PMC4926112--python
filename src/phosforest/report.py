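"""Run artifacts: networks, tables, cluster membership, and a JSON manifest.

Outputs are deterministic — re-running with identical inputs and seed yields
byte-identical TSV/JSON files — and every written file is listed in the
manifest with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import networkx as nx
import pandas as pd

from .clustering import Clustering
from .perturb import MergedNetwork


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_run_report(
    out_dir,
    merged: MergedNetwork,
    prizes: Optional[Dict[str, float]] = None,
    specificity: Optional[pd.DataFrame] = None,
    centralities: Optional[pd.DataFrame] = None,
    damage_tables: Optional[list] = None,
    targets: Optional[pd.DataFrame] = None,
    clustering: Optional[Clustering] = None,
    config: Optional[dict] = None,
) -> dict:
    """Write all run artifacts under ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    g = merged.to_graph()
    graphml = out / "merged_network.graphml"
    nx.write_graphml(g, graphml)
    written.append(graphml)

    sif = out / "merged_network.sif"
    with open(sif, "w") as fh:
        for u, v in sorted(merged.edges):
            fh.write(f"{u}\tpp\t{v}\n")
    written.append(sif)

    nodes_tsv = out / "nodes.tsv"
    rows = [
        {
            "node": n,
            "terminal": int(n in merged.terminals),
            "root": int(n in merged.roots),
            "prize": (prizes or {}).get(n, 0.0),
            "runs": ",".join(merged.node_runs.get(n, [])),
        }
        for n in sorted(merged.nodes)
    ]
    _write_tsv(pd.DataFrame(rows, columns=["node", "terminal", "root", "prize", "runs"]), nodes_tsv)
    written.append(nodes_tsv)

    if prizes is not None:
        p = out / "prizes.tsv"
        _write_tsv(
            pd.DataFrame(
                [{"protein": k, "prize": v} for k, v in sorted(prizes.items())],
                columns=["protein", "prize"],
            ),
            p,
        )
        written.append(p)
    for name, df in (
        ("specificity.tsv", specificity),
        ("centralities.tsv", centralities),
        ("targets.tsv", targets),
    ):
        if df is not None:
            p = out / name
            _write_tsv(df, p)
            written.append(p)
    for i, df in enumerate(damage_tables or []):
        p = out / f"damage_{i}.tsv"
        _write_tsv(df, p)
        written.append(p)
    if clustering is not None:
        p = out / "clusters.tsv"
        rows = [
            {"node": n, "cluster": i}
            for i, c in enumerate(clustering.clusters)
            for n in sorted(c)
        ]
        _write_tsv(pd.DataFrame(rows, columns=["node", "cluster"]), p)
        written.append(p)

    manifest = {
        "config": config or {},
        "n_nodes": len(merged.nodes),
        "n_edges": len(merged.edges),
        "n_terminals": len(merged.terminals),
        "n_steiner": len(merged.steiner_nodes),
        "roots": sorted(merged.roots),
        "modularity": clustering.modularity if clustering is not None else None,
        "files": {},
    }
    for p in written:
        manifest["files"][p.name] = _sha256(p)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
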