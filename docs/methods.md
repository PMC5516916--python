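# Methods

This note documents the models and procedures implemented in `stressnet`,
the choices made where the design was genuinely open, and what the
synthetic study conditions do and do not establish about real curated maps.

## Input model

A molecular interaction map is a CellDesigner-dialect SBML (Level 2)
process-description network: typed species (protein, complex, gene, RNA,
simple molecule, ion, drug, phenotype) and typed reactions (state
transition, association, dissociation, transcription, translation,
transport), with reaction modifiers carrying catalysis/inhibition polarity.
The reader (`stressnet.sbml_io`, built on `lxml`) consumes the
CellDesigner extension when present; plain SBML falls back to SBO-term
inference and otherwise to `unknown`/`other` classes, so third-party maps
still load. Complex components come from CellDesigner
`listOfIncludedSpecies` entries (or the package's own annotation for files
it wrote itself); a complex's gene set is defined as the union over its
components.

Two designations carry the analysis semantics and are not part of the
CellDesigner vocabulary: *stimuli* (external signals; path sources) and
*mRNAs* (stress-responsive transcripts; path targets). Precedence: sidecar
config (ids, exact names, or glob patterns) → annotation embedded by the
package's writer → a logged auto-detection heuristic (RNA species are
targets; small molecules/ions/drugs that no reaction produces are
stimuli). The heuristic is a fallback because curated maps name their
stimuli but rarely mark them machine-readably.

**Merged molecules.** Species differing only in modification state or
compartment share a reporting key: same name, same entity class, and (for
complexes, recursively) the same multiset of component keys. A merged
key's score is the maximum over member species, which preserves the [0, 1]
bound.

## Graph projections

* **Bipartite process graph** (motif analysis): molecules and reactions
  are both nodes; edges are colored `reactant` (molecule→reaction),
  `product` (reaction→molecule), `modifier` (molecule→reaction). Modifier
  polarity is deliberately dropped — the color encodes direction of
  influence, not sign. Parallel edges of identical (source, target, color)
  are forbidden; a molecule may be both reactant and modifier of one
  reaction (two colors, two edges).
* **Signaling graph** (path and controllability analyses): molecule-level
  digraph with an edge u→v for every reaction where u ∈ reactants ∪
  modifiers and v ∈ products. Rationale: mass flow and catalytic influence
  both transmit signal; a `modifiers_only` mode exists for sensitivity
  analysis. Duplicate pairs from different reactions merge into one edge
  with full provenance. Stoichiometry and multiplicity are ignored.

Transcription and translation reactions are removed *only* for motif
analysis (they would dominate every census); bow-tie and controllability
run on the full map because mRNAs are the path targets.

## Bow-tie scores

With stimuli S and mRNAs T, the bow-tie score of a node m is

    b(m) = (# simple S→T paths containing m) / (# simple S→T paths),

pooled over all (s, t) pairs with a single denominator, over directed
simple paths of at most `max_len = 30` edges. Enumeration is exact
depth-first search; a per-(s, t) cap (default 10⁷ paths) guards against
combinatorial blow-up and marks the result *truncated* rather than
raising. Paths may pass through other sources or targets. Endpoints are
scored but reported under separate roles; core calling and the binned
distribution reports cover molecule-role keys only, since endpoint scores
are trivially inflated.

Candidate bow-tie cores are molecules with b strictly greater than 0.2.
The binned report uses (0.5, 1.0], (0.2, 0.5], (0, 0.2] and {0}, i.e., the
boundary 0.5 belongs to the middle bin and 0.2 is excluded from the core
bin, consistent with the strict ">" phrasing of the thresholds.

The weighted variant multiplies each path by w(t) = |log₂FC| of its target
mRNA (a `positive`-only mode clips negative fold changes instead; the
magnitude is the default because a strongly repressed target marks an
active signaling route as well as an induced one). Targets missing from
the expression table get weight 0 and are logged; a zero total weight is
flagged, not an error.

Betweenness centrality (directed, endpoint-excluding, normalized by
(N−1)(N−2), via networkx) and total degree accompany the scores; the
score/betweenness agreement is summarized as the R² of an OLS fit, NaN
when b has no variance.

## Structural controllability

The minimum driver-node count of a directed network is N_D = max(N − |M|,
1), where M is a maximum matching of the bipartite graph whose left/right
parts are out-/in-copies of the nodes (Hopcroft–Karp, deterministic node
ordering; self-loops may match a node to itself). Drivers are the nodes
unmatched on their in-copy; with a perfect matching the lowest-id node is
the designated single driver. Because maximum matchings are not unique,
N_D, f_D = N_D/N and criticality are canonical outputs; the driver set is
reported as *one valid minimum driver set*.

A node is **critical** iff f_D computed on the graph minus that node
strictly exceeds f_D of the intact graph. The fraction rule (not raw N_D)
is authoritative: the two can disagree because N shrinks by one. The
implementation recomputes the matching from scratch per removal; on the
graph sizes involved this is cheap and trivially correct, and the test
suite holds it equal to an exhaustive-matching oracle. A consequence worth
knowing: a node is critical exactly when every maximum matching uses it,
so criticality concentrates on non-redundant relay structure (e.g., an
unbranched cascade) and avoids interchangeable wing nodes.

## Colored network motifs

Connected induced k-node subgraphs (k = 6 by default) of the bipartite
process graph are enumerated exhaustively with ESU over the undirected
skeleton — full enumeration, not sampling, for determinism and
oracle-testability. Each subgraph is canonicalized into a
permutation-invariant signature over node kinds and the 3-color adjacency;
the search runs only over permutations within refined invariant classes
and is verified against an all-permutations oracle in the tests.

The null model switches heads between two same-color edges (rejecting
duplicates), preserving every node's per-color in- and out-degree and
bipartiteness; 10×|edges of that color| attempted swaps per color per
replicate. Significance per signature against `n_random` nulls (100 by
default): empirical one-sided p = fraction of nulls with count ≥ real,
z = (real − null mean)/null sd with sd = 0 mapped to +∞ (real > mean) or 0,
and the motif call requires p < 0.05 AND z > 2 AND real count ≥ 5.

Cross-map calls: *common* motifs are significant in every non-reference
map; *specific* motifs are common motifs present in all positive reference
maps and absent from all negatives, where reference "presence" is either
full significance or mere frequency (count ≥ 5) — both supported because
published practice is ambiguous on this point. A monocolor mode forgets
edge colors (classes can only merge) to quantify what the coloring buys.

## Phenotype statistics

Critical genes are the genes of at least one critical protein or complex
node; the non-critical universe is the genes of the map's remaining
protein/complex nodes (within-map framing, not genome-wide). Tests:
chi-square without continuity correction (Fisher exact always available as
a robustness flag), two-tailed Mann–Whitney U (exact null for combined
n ≤ 20 without ties), paired t across per-map fraction pairs, Welch's t
for continuous annotations, and the gTOW dosage-sensitivity report
(fraction with copy-number limit ≤ 10, Fisher 2×2). Genes absent from the
annotation table are excluded and tallied in the log. Degenerate inputs
(empty margins, zero-variance differences) return flagged results, not
exceptions; identical groups yield the maximal p.

## Synthetic study conditions

`gen_stress_map` plants a layered bow-tie: stimuli → upstream sensors →
core → downstream effectors → transcription of mRNA targets, with no
skip edges, so every stimulus→target route traverses the core. Defaults:
8 stimuli, 40 intermediates (split 20/20), 5 core molecules, 30 targets,
wing edge density 0.3 (each wing node keeps ≥ 1 in- and out-edge).

The core is a **cascade**: all upstream sensors feed its first element and
its last element fans out downstream, the way the sequential kinases of a
MAPK-type pathway sit on essentially every path. Planted core nodes
therefore have b(m) = 1 exactly and are unavoidable cut nodes — the
analytically predictable margin that makes planted-core recovery a sharp
test. This is the extreme of the architecture; real maps show graded core
scores (roughly 0.2–1.0), so recovery on these fixtures demonstrates the
scoring machinery, not performance on noisy real topologies.

With probability `p_complex` a wing/core node is a two-component complex;
with probability `p_reversible_inhibitor` a core node receives a
*reversible complex-formation module*: inhibitor + target ⇌ inactive
complex (association and dissociation reactions), a private small-molecule
trigger as dissociation modifier (the cAMP-releases-the-inhibitor
pattern), and the inhibitor:target abundance ratio stored as species
metadata. With the trigger the module is an exact six-node colored
substructure whose signature is computed (never hard-coded) by building
the module in isolation.

`gen_expression` draws upregulated targets' log₂FC from N(mu, sigma)
(defaults 2.0, 0.5) and the rest from N(0, baseline_sigma = 0.2) —
magnitudes typical of stress-response inductions. `gen_annotations` draws
per-gene Bernoulli lethality (default 0.2, matching the ~20% essentiality
of single-gene deletions), group-dependent Bernoulli synthetic lethality
(defaults 0.6 critical / 0.3 non-critical), group-dependent Poisson
negative-interaction counts (defaults 4 / 1) and log-normal copy-number
limits independent of criticality. All generators are reproducible from a
single integer seed.

What the synthetic conditions do **not** emulate: the degree distribution,
state-variant richness and reaction-type mix of curated maps; annotation
noise and ascertainment bias of genome-wide screens; kinetics of any kind.
Green tests on these fixtures validate the algorithms and their
statistical calibration, not biological conclusions about any organism.

## Problem sizes and reproducibility

The analysis scripts and the acceptance script run on desk-scale problem
sizes chosen so exhaustive enumeration stays exact: default maps of ~130
species enumerate ~8,000 connecting paths in well under a second; the
motif fixture (110-node bipartite graph) enumerates ~12,000 six-node
subgraphs per replicate, and the panel analyses use 10–20 switch-null
replicates per map where the standard choice is 100 (the parameter is
`n_random`; nothing else changes). Every random draw flows from explicit
integer seeds; two runs with the same seed produce byte-identical tables.

## Known limitations

* Simple-path counting is worst-case exponential; the cap merely flags
  truncation. Real curated maps of ~1,000 species can take minutes–hours.
* Only one maximum matching is examined; "possible vs always" driver
  classification would require enumerating all maximum matchings.
* The canonical-form search is exact but unoptimized beyond invariant
  refinement; k > 8 is out of scope.
* The SBML writer emits the dialect subset the reader consumes (plus its
  own annotation namespace); it is not a general CellDesigner authoring
  tool and does not write layout, MIRIAM annotations, or SBML Level 3.
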