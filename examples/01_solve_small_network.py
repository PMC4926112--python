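"""Solve a tiny receptor-rooted PCSF instance by hand.

A receptor EGFR can reach two phosphorylated proteins (MAPK1, STAT3) through
an adaptor GRB2.  The solver weighs the beta-scaled prizes of the terminals
against the edge costs (1 - confidence) plus the omega cost of opening a
tree, and returns the optimal forest.
"""

from phosforest import (
    Interactome,
    PCSFConfig,
    augment_with_root,
    make_receptor_set,
    solve_pcsf,
)

net = Interactome.from_edges(
    [
        ("EGFR", "GRB2", 0.95),
        ("GRB2", "MAPK1", 0.90),
        ("GRB2", "STAT3", 0.70),
        ("EGFR", "STAT3", 0.60),
    ]
)
receptors = make_receptor_set(["EGFR"], net)
prizes = {"MAPK1": 1.2, "STAT3": 0.8}
config = PCSFConfig(beta=2.0, omega=0.001, depth=10, seed=0)

aug = augment_with_root(net, receptors, config.omega)
forest = solve_pcsf(aug, prizes, config)

print(f"objective  : {forest.objective:.4f}")
print(f"trees      : {forest.kappa} rooted at {forest.roots}")
print(f"nodes      : {sorted(forest.nodes)}")
print(f"edges      : {sorted(forest.edges)}")
print(f"orientation: {forest.oriented_edges()}")
# The objective sums excluded prizes (none here: both terminals are cheap to
# reach), the chosen edge costs, and omega for the single tree.  Edges point
# away from the receptor, giving the implied signaling direction.
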