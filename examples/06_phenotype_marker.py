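"""Find a Steiner node whose presence pattern tracks a phenotype.

A marker node is planted so that it enters the per-line networks exactly in
the phenotype-positive samples.  Ranking Steiner candidates by agreement
with the phenotype pattern — breaking ties by the chance probability of the
pattern in random networks — recovers the marker at rank 1.
"""

from phosforest.benchmark import phenotype_marker_rank, phenotype_scenario

scenario = phenotype_scenario(seed=0)
print("phenotype pattern:", scenario.phenotype)
rank, table = phenotype_marker_rank(scenario, n_random=15, seed=0)
print(f"planted marker {scenario.marker!r} ranks {rank}")
print(table.head(5).to_string(index=False))
# agreement counts the lines where a node's observed presence equals the
# phenotype; chance_probability is how often random networks would reproduce
# the phenotype pattern for that node (smaller = more significant).
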