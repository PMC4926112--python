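# Methods

## Model

The package reconstructs signaling networks as receptor-rooted
prize-collecting Steiner forests. The input is an undirected interactome
whose edges carry confidence scores *s_e* ∈ (0, 1]; costs are *c_e = 1 −
s_e*, so minimizing a sum of costs prefers likely interactions (for
log-likelihood-based scores, minimizing cost sums maximizes a product of
likelihoods). Prized proteins ("terminals") are the phosphoproteomic hits;
the objective

    f′(F) = β · Σ_{v∉V_F} p(v) + Σ_{e∈E_F} c(e) + ω · κ

trades the β-scaled penalty for excluding prizes against edge costs and a
per-tree opening cost ω (κ = number of trees). Constraining every tree to
be rooted at a cell-surface receptor adds implicit directionality: an
artificial root v₀ is connected to every receptor with an edge of cost ω,
a single depth-bounded tree containing v₀ is optimized on the augmented
graph, and removing v₀ yields the forest — the tree formulation and the
forest formulation have the same optima (checked exhaustively on small
instances in the test suite). The depth bound D counts edges from v₀, so a
root receptor sits at depth 1; we enforce it for **all** forest nodes, not
only terminals, which is slightly stricter and never admits an infeasible
terminal.

### Prizes

A phosphosite row of per-channel intensities is normalized to the mean of
all channels; the prize of a protein in a sample is the maximum over its
sites of |log₂ fold change| (log base configurable). Prizes are invariant
to rescaling a site's intensity row. A site whose fold change is exactly 0
(empty channel) would have infinite |log|; it contributes a configurable
cap (default 10) instead, and a protein whose *every* site reads 0 in a
sample is treated as unobserved there and excluded from the terminal set.
Zero-prize proteins are excluded from the terminal set. Receptors may
carry prizes and are then treated like any terminal.

### Parameters

| parameter | default | meaning |
|---|---|---|
| β | 2.0 | prize scale; larger β collects more terminals, β = 0 gives the empty forest |
| ω | 0.001 | cost of opening a tree (root-edge cost); larger ω merges trees |
| D | 10 | maximum edges from v₀ to any forest node |
| threshold | 0.5 | minimum edge confidence kept during preprocessing (inclusive) |
| restarts | 16 | heuristic solver restarts; lower values trade quality for speed |
| prize cap | 10 | substitute for infinite |log FC| at empty channels |

Duplicate interactome rows collapse to the maximum score; self-loop rows
are skipped with a warning; identifiers are opaque case-sensitive strings.

## Solvers

**Exact.** Every subtree of the augmented graph that contains v₀ is
enumerated exactly once (branch on the lowest-index frontier edge,
permanently forbidding the alternatives at each level), pruned by the depth
bound, and scored incrementally. Ties are broken deterministically: fewer
trees, then fewer edges, then lexicographically smallest node list. The
enumeration is feasible up to a configurable cap (default 20 augmented
edges) and is itself validated in the tests against a structurally
unrelated brute force over all edge subsets.

**Heuristic.** A seeded multi-restart local search over rooted trees:

1. *grow* — repeatedly attach the best-utility path from the tree to a
   prized node (multi-source Dijkstra over (cost, depth) states with Pareto
   pruning, so a loose depth bound costs almost nothing); paths with
   positive true gain are always taken, and a per-restart *slack* budget
   admits temporarily negative paths to climb over the cost hump of opening
   a tree — strong pruning later discards bets that do not pay off;
2. *reattach* — move any node to a strictly cheaper parent edge,
   depth-permitting;
3. *evict-and-reconnect* — detach a subtree, credit the unprized ancestor
   chain its removal would strand, and re-hang the subtree (re-rooted at
   whichever of its nodes is reached) via the cheapest prize-collecting
   path from the rest of the tree; applied transactionally (apply, prune,
   keep only if the true objective improved) to prevent oscillation;
4. *strong pruning* — drop every subtree whose net utility does not cover
   its connecting edge; at the root this also decides tree openings, and on
   exact ties drops, preferring smaller solutions.

Restarts diversify the search: selection weights alternate between raw
costs and prize-discounted costs (which reveal prize-rich detours that
plain Dijkstra dominates away), cycle through slack levels 0/1/2 ×
(ω + mean edge cost), funnel growth through each receptor in turn (so
alternative roots are explored even when greedy growth never picks them),
and add multiplicative lognormal jitter (σ = 0.2) beyond the first six.
Gains and objectives are always evaluated with true costs; the final answer
is the best restart under the exact solver's tie-break, never worse than
the empty forest. The heuristic matches the exact optimum on all tested
random instances within the exact cap (three instance families, 300+
instances, and the 200-instance suite in the acceptance tests); this is a
tested contract, not a guarantee.

Determinism: all randomness flows from numpy seed sequences keyed by
(config seed, restart index); identical inputs and seed give identical
forests, and ensemble replicate k is reproducible from (master seed, k)
alone.

## Knockout cascade

A solution connects each downstream node to exactly one receptor, hiding
cross-talk. The cascade therefore: (1) solves the wild type; (2) knocks
out, one at a time, every receptor used as a root — and, to closure, any
new root that surfaces in a single-knockout solution; (3) knocks out every
unordered pair of receptors observed as roots across those solutions; and
(4) merges all solutions by node/edge union, recording per-node provenance
and labeling prize-carrying nodes terminals and the rest Steiner nodes.
Knocking out all receptors rather than only used roots is available behind
a flag; only used roots can change the root structure, so the default is
the economical choice. A knockout that leaves nothing profitable
contributes an empty forest, not an error.

## Randomization and phenotype probabilities

Null ensembles keep the observed prize multiset and terminal count but
assign the prizes to uniformly resampled node sets (receptors are eligible
by default; a flag excludes them). Every replicate runs the same cascade
and merge procedure as the observed data. With n = appearances of a node
in N replicates, prob = n/N and specificity = 1 − prob.

For a binary phenotype over L samples, the probability that a node matches
the pattern by chance is the product over lines of prob (presence required)
or 1 − prob (absence required), treating replicate draws across lines as
independent; this equals exhaustive enumeration over all N^L replicate
combinations (verified in the tests at N = 10, L = 3), and an any-node
summary 1 − Π(1 − P_match) is attached. Marker ranking sorts candidate
Steiner nodes by observed agreement with the phenotype, then by ascending
chance probability.

## Target ranking

Centralities (degree, betweenness, eigenvector, pagerank, closeness — the
classical undirected forms, computed with networkx on the merged network
with interactome edges restored) contribute their top-k lists (k = 50 by
default; ties broken by score then node id). Path damage is computed two
ways: *directed* — the fraction of receptor→terminal simple paths through a
node, enumerated exhaustively along the forests' orientations up to a
length cap (default D); *undirected* — a path pool holding, per
receptor–terminal pair, the cost-weighted shortest path plus every
alternative obtained by deleting one of its edges at a time. Receptors and
terminals themselves are not removal candidates. The target list is the
union of per-measure top-k sets; damage-based entries additionally require
randomization probability < 0.5.

## Clustering and reports

Before clustering, all interactome edges between solution nodes are
restored. Girvan–Newman divisive clustering removes the
highest-betweenness edge (ties broken by edge id, making the dendrogram
input-order invariant) and returns the maximum-modularity partition
(default) or the first partition with ≥ k components; betweenness is
unweighted by default with a cost-weighted mode behind a flag. Run reports
write GraphML/SIF networks and TSV tables deterministically, with SHA-256
checksums in a JSON manifest; identical inputs and seed give byte-identical
outputs.

## Synthetic scenarios

The generator emulates the shape of a multi-channel tumor phosphoproteomics
study, not its biology. A scale-free (preferential-attachment) or
Erdős–Rényi background interactome carries Beta-distributed scores rescaled
into (0.5, 0.9] — the regime that survives the standard 0.5 confidence
filter, as with a pre-thresholded interaction database. Planted pathways
are receptor → bottleneck → split → leaves trees (leaf depth 3): leaves are
recycled background proteins, while interior nodes are dedicated adaptors
whose only interactions are the pathway edges (score 0.97) — modeling
pathway-specific signaling intermediates rather than promiscuous hubs. The
first pathway is larger (two splits, twice the leaves) and its bottleneck
gets a backup receptor at score 0.95, so a single knockout re-roots the
same subtree — the canonical shared-pathway situation.

Phosphosite simulation: each leaf gets 1–3 sites whose channel pattern is
`effect_size` in the pathway's active samples and the mean-preserving
complement elsewhere, times lognormal noise (σ = 0.05 by default, a
reproducibility typical of well-run isobaric labeling); with zero noise the
active fold change is exactly `effect_size` after channel-mean
normalization. This encodes the real coupling of channel normalization: a
leaf active in k of S samples necessarily shows a reciprocal deviation in
the other samples, so "inactive" lines carry small but nonzero prizes. A
configurable fraction of background proteins receives pure-noise sites.
The default recovery scenario uses 90 nodes, 8 receptors, 3 pathways,
effect 4, noise 0.05, 8 channels.

**Phenotype marker.** The marker scenario attaches a fresh Steiner node to
the first bottleneck behind moderate-confidence edges (score 0.52, cost
0.48), with one fresh leaf per phenotype-positive line, each active exactly
in its line (single site, effect 2.0). The chain cost for both leaves
(≈1.44) sits between the combined reciprocal payoff in negative lines
(≈0.89) and the payoff in a positive line (≈2.44), so the marker enters the
per-line solution exactly in positive lines; base pathway activities are
kept at Hamming distance ≥ 2 from the phenotype so no planted competitor
can match the pattern. These margins are design calculations, not fitted
values.

**Specificity property.** The hub-versus-planted specificity contrast is
demonstrated on its own scenario: 250 nodes, ~25 terminals, background
scores 0.5–0.75 and planted scores 0.8. When planted edges are nearly free
relative to background (as in the recovery scenario), the planted pathway
acts as a cheap entry ramp from the artificial root and genuinely appears
in most null networks — the specificity index exists precisely to flag
such topology-driven nodes. The moderated confidence gap is the regime in
which planted intermediates are data-driven and the property (planted
Steiner specificity > hubs', and > 0.5) holds.

**What passing these benchmarks does and does not show.** The scenarios
verify that the machinery — prize assignment, rooted solving, knockouts,
nulls, ranking — behaves as designed when the ground truth is known and
the signal is strong. They do not model identifier ambiguity, missing
interactome coverage, correlated mass-spectrometry noise, or biological
pathway overlap, so performance numbers on them do not transfer to real
data.

## Benchmark and reproduction sizes

The test suite and `scripts/acceptance.py` use: 200 random instances
(8–10 nodes, ≤ 17 augmented edges) for solver-optimality agreement; 50
instances for β = 0; 8 instances × 6-point β grid and × 5-point ω grid for
the monotonicities (exact solver); 40 heterogeneous instances for forest
validity; 100 random digraphs (≤ 15 nodes) for damage-ratio agreement
against literal DFS enumeration; 20 seeds of the recovery scenario (median
F1 and bottleneck top-rank rate, with the directed-damage path cap at 4 =
planted depth + 1, below which knockout-reroute braids would swamp the
counts); and 10 seeds × 8 lines × 15-replicate ensembles for the phenotype
marker (replicates at 2 restarts, observed lines at 4). These sizes keep a
full reproduction run in the minutes range on a single CPU while leaving
each check statistically meaningful.

## Known limitations

* The heuristic has no approximation guarantee; its quality is established
  empirically against the exact solver on small instances only.
* Exhaustive simple-path enumeration for directed damage is exponential;
  the length cap (default D) bounds it, and very dense merged networks may
  still be slow.
* The exact solver's monotonicity properties (prize mass in β, κ in ω)
  hold under its deterministic tie-break; they are not asserted for the
  heuristic.
* Identifier normalization across databases, site-localization scoring and
  cross-run normalization are out of scope; inputs are taken at face value.
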