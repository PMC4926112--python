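"""Expose receptor cross-talk with in-silico knockouts.

Two receptors share a downstream pathway; the plain solve uses only the
cheaper one.  Knocking out receptors one by one (then in pairs) and merging
all solutions keeps both receptors in the final network — the root-switch
behavior that reveals shared pathways.
"""

from phosforest import (
    Interactome,
    PCSFConfig,
    ko_cascade,
    make_receptor_set,
    merge_solutions,
)

net = Interactome.from_edges(
    [
        ("EGFR", "SHC1", 0.95),
        ("PDGFRB", "SHC1", 0.85),
        ("SHC1", "MAPK1", 0.9),
    ]
)
receptors = make_receptor_set(["EGFR", "PDGFRB"], net)
prizes = {"MAPK1": 5.0}
config = PCSFConfig(beta=1.0, omega=0.001, depth=10, seed=0)

results = ko_cascade(net, prizes, receptors, config)
for res in results:
    print(f"{res.label:15s} roots={res.roots} nodes={sorted(res.forest.nodes)}")

merged = merge_solutions(results, prizes)
print(f"\nmerged network: {sorted(merged.nodes)}")
print(f"terminals     : {sorted(merged.terminals)}")
print(f"steiner nodes : {sorted(merged.steiner_nodes)}")
# The wild type roots at EGFR only; the EGFR knockout re-roots the same
# subtree at PDGFRB, so the merged network contains both receptors.
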