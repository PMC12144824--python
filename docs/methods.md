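# Methods

## Genome model

Genomes are graphs on marker extremities and telomeres. Marker edges pair
each marker's tail and head; adjacency edges form a perfect matching on
extremities plus telomeres, making every component a linear chromosome
(path between two telomeres) or a circular chromosome (cycle). Homology is
an equivalence on markers given by string family labels; a *resolved*
homology (a matching) pairs each marker with at most one marker of the
other genome. Degenerate genomes drop the matching requirement on
adjacencies and model uncertain ancestors; a linearization is a
conflict-free sub-selection of their adjacencies covering every extremity.

Marker identifiers are unique within a genome; wherever two genomes meet
(comparison diagrams), vertices are tagged with their genome side, so
self-comparisons and cross-file identifier collisions are safe. In the
UniMoG-style text format, the k-th occurrence of a family name across a
file becomes marker `family_k`; `|` ends a linear and `)` a circular
chromosome. Candidate adjacencies travel as TSV
(`genome marker1 side1 marker2 side2 [weight] [flag]`, side `o` = telomere,
default weight 0); trees as Newick with mandatory internal labels
(redundant unary root wrappers are collapsed). These dialects are package
conventions — the underlying theory fixes no file formats.

## Pairwise distance

The capping-free comparison diagram of genomes A and B has adjacency edges
from both genomes, extremity edges between homologous extremities, and
self edges (the marker edge) on markers without a partner. Under a
resolved homology the diagram splits into cycles and paths once self edges
are ignored; paths are labeled by their two ends — uppercase `A`/`B` for
telomeres, lowercase `a`/`b` where the only continuation would be a self
edge — and the DCJ-indel distance is

    d = n − c + ceil((p_ab + max(p_Aa, p_aB) + max(p_Ab, p_Bb) − p_AB)/2) + s

with `n` matched markers, `c` cycles and `s` circular singletons (cycles of
alternating adjacency and self edges, each costing one indel). Components
labeled `AA`, `BB`, `aa` or `bb` carry coefficient zero. We verified this
coefficient choice — and the implementation as a whole — against an
independent operation-level oracle (below) on hundreds of randomized tiny
instances.

Under the maximum matching model the distance minimises the formula over
all per-family maximum matchings. Two oracles implement this definition
independently of the ILP:

* `distance_max_matching` enumerates all maximum matchings (products of
  per-family injections) and minimises the census formula — exponential,
  guarded by an explicit budget, intended for tiny instances;
* `bfs_operation_oracle` performs a bidirectional breadth-first search over
  genome space, one search per maximum matching, with moves being DCJs
  (cut two adjacencies and rejoin, telomere-aware, plus single cuts) and
  indels restricted to markers singular under the fixed matching. Genomes
  are compared as chromosome multisets up to marker renaming. The matching
  must be fixed per search: allowing indels to touch any family member
  would let a scenario delete a matched copy and re-insert a fresh one,
  undercutting the model's distance (observed on randomized tests).

## The ILP

The program follows a two-level structure. The *global level* assigns each
extremity/telomere a presence bit `g_v`, ties tail and head presence
together, bounds per-family copy numbers `L ≤ Σ g ≤ H` (defaulting to
"every candidate marker occurs"), and requires each present vertex to sit
in exactly one selected candidate adjacency — which is precisely a
linearization. Leaf genomes are non-degenerate, so their selections are
fixed outright.

The *local level* instantiates, per tree branch, decomposition variables on
the comparison diagram of the two (degenerate) genomes: adjacency-edge
selection is inherited from the global level by variable identity; one
binary per candidate marker pairing drives both sibling extremity edges
(making tail/head consistency structural); self edges exist for every
marker, restricted per family to one genome side by a side-selector bit
`b_f` — together with the per-extremity coverage constraint this enforces
the maximum matching model. When the copy-number bounds already determine
which side of a family is overrepresented, the underrepresented side's
self edges are dropped and `b_f` omitted.

Components are counted by reports:

* Each vertex has a potential `y_v ∈ {0..rank(v)}` equalised along selected
  adjacency/extremity edges and forced to zero by a selected self edge.
  A claim bit `z_v` requires `y_v` to reach the vertex's own rank, so each
  component can claim at most once, at its minimum-rank vertex. Ranks order
  telomeres of A, telomeres of B, extremities of A, extremities of B: the
  minimum-rank vertex of every cycle is then an A-extremity (cycle report
  `r^c`) and of every telomere-to-telomere path a telomere (AB report,
  guarded so same-genome telomere paths cannot claim).
* A genome-side label `l_v` (0 on A-telomeres and A-side indel ends, 1 on
  B-telomeres and B-side ends) propagates along selected edges and may flip
  only where a report is paid: at an A-side indel end (`r^ab`, guarded by
  that marker's self edge) or at a telomere (`r^{Ab}`, `r^{aB}`, …, guarded
  by the neighbour's label so each path class reports truthfully). Paths
  whose potential collapsed to zero force their telomeres to report.
* Counters assemble the distance: `f = n − c + q + s` with `2q ≥ p_ab +
  max-terms − p_AB` and the maxima relaxed as `≥` inequalities — tight
  under minimisation pressure whenever `α > 0`.

Circular singletons are counted in one of two interchangeable encodings.
*Enumeration* lists candidate cycles of alternating candidate adjacencies
and self edges (depth-first, canonicalised at the minimum-rank extremity)
with one indicator each; it is used while the candidate count stays within
twice the number of self edges. Beyond that threshold — dense candidate
sets have exponentially many singleton candidates — a *counting gadget*
takes over: an orientation bit `d_v` flips across every selected edge, a
potential `w_v` must rise along the orientation across selected adjacencies
and stay level across selected self edges, so every closed alternating
cycle must pay a report somewhere. Two implementation details matter: the
rise constraints are emitted for both orientations of each adjacency edge
(one direction alone misses cycles), and the level constraint across self
edges is conditioned on the self edge being selected — unconditional
coupling would force a spurious report on a matched one-marker circular
chromosome. The gadget's big-M is the self-edge count plus two.

Every variable and constraint count is a constant per diagram vertex/edge
(enumeration is capped at the linear threshold), so the program size is
linear in the total size of all comparison diagrams; a regression across a
fourfold size range asserts this.

The objective minimises `Σ_E α·f_E − (1−α)·w_E`, where `w_E` sums the
weights of the adjacencies selected at the branch's two endpoint genomes
(an internal genome's weights count once per incident branch). An optional
emulation mode reduces every telomeric adjacency's weight by a constant,
reproducing formulations with an explicit telomere penalty: their defaults
α′ = 1/2, β′ = 1/4 map to α = 2/3 with telomere weight reduced by 1.

Decoding reconstitutes one proper genome per node (validated against the
genome invariants), recomputes every branch distance independently through
the component census of the selected decomposition, and cross-checks the
solver's distance variables and objective — at optimality any discrepancy
raises. The ILP optimum was verified to equal the exhaustive
maximum-matching distance and the operation-search distance on large
randomized sweeps of tiny instances, including singleton-heavy and mostly
circular ones.

## Solver

Models are held in a neutral named-variable form, exportable to the LP file
format, and solved through scipy's HiGHS interface, which runs
single-threaded and deterministically (thread and seed arguments are
accepted for interface stability). HiGHS cannot ingest an external
incumbent through this interface, so a supplied warm start is validated
against every constraint and kept as a certified fallback incumbent in case
the solver run is cut off; time limits return the best incumbent with its
gap rather than raising.

## Linearization and augmentation

Weighting each candidate adjacency by the number of marker extremities it
touches turns linearizability into maximum-weight matching: the genome is
linearizable iff the optimum weight equals the extremity count, and the
matching itself is the linearization. Candidate weights enter as a
secondary objective (scaled below the coverage term) so ties break toward
heavy adjacencies, as the warm-start construction requires.

Local-guarantee augmentation decomposes the degenerate genome into
connected components (marker plus adjacency edges) and adds a telomere per
extremity only in components that are not locally linearizable. The shape
test — even vertex count and simple path / simple cycle / adjacency edges
forming a complete graph — is supplemented by the requirement that the
component's adjacency edges contain a perfect matching, which is the actual
certificate that a local linearization exists (an even path of marker edges
alone would otherwise slip through and leave the genome unlinearizable).
The check is conservative: failing components are augmented, never the
reverse. Safer mode skips the analysis and offers *every* extremity its own
telomere (idempotently, at configurable weight, default 0), so no wrong
candidate adjacency is ever forced into a solution merely to preserve
linearizability.

## Pre-processing

The warm start linearizes every ancestor with the weight-aware matching,
then decomposes each branch diagram greedily: alternating cycles are
enumerated up to eight edges and fixed shortest-first when their pairings
are mutually consistent, after which each family's matching is completed
arbitrarily to maximum (any feasible completion is acceptable — the warm
start only needs feasibility, which is asserted constraint-by-constraint).
Leaf-pair lower bounds add, for every pair of leaves, `Σ f_E ≥ d(A,B)`
along the connecting path, justified because intermediate genomes can only
add operations; they never change the optimum, only the bound. Both
features default to off: measured on this package's own instances, their
cost generally exceeds their benefit.

## Simulator

The simulator evolves a root genome of `N` single-copy markers (default
100, two chromosomes, linear) down a fixed topology — default the balanced
four-leaf tree `(((A,B)F),((C,D)G))Root` — applying a fixed number of
operations per branch (default 30) drawn by rate: duplication 0.4, deletion
0.2, insertion 0.1, remainder DCJ. Segment lengths follow Zipf laws
(parameter 6.0 for duplications, 4.0 for indels), truncated at 20 since the
support is otherwise unbounded. Duplications copy segments tandem-free with
fresh marker ids in the same families; insertions introduce fresh
single-copy families; DCJs cut two random adjacencies and rejoin (with
occasional single cuts so telomere counts drift). Candidates at internal
nodes are the true adjacencies plus `k` adversarial noise adjacencies
(default 30) drawn uniformly from non-true extremity pairs. Identical seeds
give byte-identical ground truths.

What the simulator does *not* emulate: gene-tree/species-tree discordance,
reconciliation artefacts, rate heterogeneity across branches, sequence-level
noise in homology assignment, or biased adjacency-inference errors —
noise here is uniformly random, which is adversarial for weighting but
structurally easier than correlated errors from real inference pipelines.
Passing tests therefore certify the optimizer and its model, not the
end-to-end accuracy of any particular annotation pipeline.

Scoring compares recovered and true ancestral adjacency sets per internal
node (orientation-insensitive keys; telomeric adjacencies keyed by their
marker extremity, with augmentation-added telomeres excluded from the
recovered set unless the truth ends a chromosome at the same extremity;
include/exclude-all modes available). Precision on an empty recovery is
defined as 1 and flagged. Means over nodes and pooled aggregates are both
reported.

## Problem sizes used in the checks

The randomized verification sweeps run on instances small enough for the
exhaustive oracles to be exact: genome pairs of up to 5 markers over 4
families for the three-way distance agreement (100 pairs), degenerate
genomes of up to 10 candidate adjacencies for the linearizability
equivalence (200 genomes), four-leaf simulations of 10–15 root markers with
3–5 operations per branch and up to 10 noise adjacencies for the
small-parsimony and safer-mode checks, and emission-only instances of
10–80 markers for the size regression. These sizes were chosen so each
property is tested at full strength by exact reference computations.

## Known limitations

* The pairwise-distance oracles are exponential by design and refuse large
  inputs explicitly rather than degrade silently.
* `initial_solution` supports only copy-number bounds that admit keeping
  every candidate marker (the greedy linearization keeps all markers).
* The ILP reports path classes only up to the formula's max-structure
  (e.g. an `Aa` path may be booked as `Ab` when both maxima leave the
  distance unchanged); decoded distances are therefore recomputed from the
  census, never read off the report variables.
* Chromosome-count drift in the simulator depends on the DCJ mix; the
  single-cut share (0.1 of DCJs) is a modelling choice, not an estimate.
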