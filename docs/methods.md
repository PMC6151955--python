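# Methods

This note documents the models, parameter choices, numerical details,
and known limitations of `supercoord`, in the order of the pipeline.

## Data model and coordinate conventions

All genomic coordinates are 0-based, half-open, and refer to the
forward strand; a row's `strand` field only records its reading
direction inside the block. MAF reverse-strand rows (start s, size n,
source size L) are normalized on input to [L−s−n, L−s). Global
supergenome coordinates are 1-based internally, matching the interval
[1, n] of the coordinate function, and exported 0-based half-open in
the BED-like mapping table.

Block projections onto an assembly collapse overlapping intervals on
one contig into a single forward-strand interval; intervals on
different contigs never merge, and intervals that merely touch stay
separate. Blocks surviving the filters carry at most one interval per
assembly, which makes the per-assembly interval order total per contig
and the predecessor relation well defined.

## Input curation

Three stages, in this order, with these defaults:

| stage | rule | default | rationale |
|---|---|---|---|
| length | drop blocks with ≤ `min_block_len − 1` columns | 11 (i.e. length ≤ 10 nt removed) | very short blocks are spurious matches or gap bridges |
| score | drop blocks with score/(C(r,2)·ℓ(B)) < threshold | −30 | −30 per column pair is the blastz gap-extension penalty; a block scoring exactly −30 is indistinguishable from pure gap extension and is **kept** (the threshold is the stated limit) |
| overlap | per assembly+contig, across distinct blocks: border overlaps ≤ tolerance ignored; larger overlaps tag both intervals; complete containment tags both regardless of size; blocks with ≥ 1 tagged interval removed | 20 nt | short border overlaps come from overlapping extensions of local alignment seeds and do not disturb block order; duplications and spurious rematches do |

The overlap stage runs only after the first two, so low-quality blocks
cannot veto good ones. The tolerance applies **per overlapping pair**,
not cumulatively per interval — the alternative reading is possible but
the pairwise rule is the direct one. "Length" of a block is its column
count ℓ(B), the only length defined for a block. Blocks without a
score (or with a single row, where no pair exists) are exempt from the
score stage and counted in the report; synthetic data may not carry
meaningful scores. Residual border overlaps survive filtering by
design and are resolved only at coordinate assignment, by truncating
the later block's overlapping prefix (the earlier block keeps the
positions), which preserves injectivity of the map.

## The supergenome graph and the cost function

Vertices are blocks; for each assembly and contig the start-sorted
intervals contribute one directed edge per consecutive pair, colored by
assembly and labeled with the contig. Equal start positions cannot
occur after filtering and raise an error. The full betweenness cost
b(ρ) sums, over every assembly and every triple of blocks co-occurring
on one contig, an indicator that the genomically middle block is not
between the other two in ρ. It is cubic and used only by the oracle
and the tests; production metrics use the graph-local restriction
𝒞(Γ̂): triples (i, j, k) formed by two same-colored edges {i,j}, {j,k}.
Blocks whose projection on a contig is not a single interval (possible
only pre-filtering) are excluded from the cost triples.

The exact solver enumerates all permutations with numpy (positions of
all permutations are materialized as one int8 array; each triple is a
vectorized comparison), refuses instances above 9 blocks, and breaks
ties by lexicographic id order. An independently coded scalar brute
force cross-checks it in the test suite.

## Simplification

Three reductions are iterated to a fixed point; each preserves the
expanded block set (vertices only merge, never vanish), never adds
edges, and strictly reduces vertices + edges when it fires, so
termination is immediate. All tie-breaks are lexicographic on vertex
ids; there is no randomness anywhere in the pipeline.

* **Source/sink contraction.** A source with exactly one distinct
  successor is placed immediately before it; sinks symmetrically.
  Isolated vertices are untouched.
* **Superbubble contraction.** Minimal single-entrance single-exit
  acyclic subgraphs with isolated interior are found by the standard
  forward search on the color-blind simple digraph (parallel edges
  collapse for topology, but remain as evidence) and replaced by one
  vertex whose internal order is the evidence-sorted topological order
  of the subgraph. A plain edge is not a bubble (the source/sink rule
  covers chains); an empty-interior bubble requires at least two
  parallel edges. Interiors containing directed cycles — including
  bidirectional pairs — are rejected by the search itself, so
  unresolved mini-cycles can never sit inside a contracted bubble.
  Innermost bubbles are contracted first; nested contraction expands
  to the same block order as contracting the flattened bubble.
* **Mini-cycle resolution.** Mini-cycles (vertex pairs connected in
  both directions) are grouped into maximal vertex-sharing complexes —
  provably a partition with pairwise vertex- and edge-disjoint classes
  — and each complex is resolved independently. Adjacencies are
  decided greedily: support is the pair (total multiplicity, direction
  bias max(fwd,bwd)/(fwd+bwd)) with lexicographic tie-break; once any
  adjacency is decided, adjacencies touching decided vertices are
  preferred (propagation), in descending support. An adjacency with no
  majority adopts the direction pointing away from its already-decided
  endpoint; a direction that would close a directed cycle among the
  decided edges is replaced by its reverse. After all decisions, every
  edge in a losing direction is deleted. A color path crossing a
  boundary between oppositely oriented regions inside the complex
  necessarily traverses some decided adjacency in the losing direction,
  so boundary edges are removed by the same deletion — no separate
  pass is needed. Directed cycles not inside the complex are left
  intact. The "region" in which support is evaluated is the complex
  itself together with the edges incident to its vertices: the smallest
  self-contained choice, since the definition of the support
  neighborhood is genuinely open.

The scheduler runs source/sink + superbubble to a joint fixed point,
then one mini-cycle pass over all current complexes, and repeats while
that pass removes any edge. Whole-genome orientation flips are realized
only as the per-complex orientation decisions above; a global search
for the optimal orientation assignment would itself be as hard as the
ordering problem.

## Feedback arcs and DAG post-processing

Remaining directed cycles are broken with the greedy linear-time
ordering (peel sinks right, sources left, otherwise move the vertex
with maximal out−in weight difference left; ties to the smallest id).
Edge multiplicities act as weights: a direction observed in more
genomes is more expensive to cut. All edges pointing leftward in the
resulting sequence are removed; the removed weight never exceeds half
the total. After cycle removal the plain simplifiers run again, then a
generalized source/sink pass valid only on DAGs: a source s whose
successor v reaches every other successor of s is placed immediately
before v (sinks analogously), iterated to a fixed point. The
generalized rule subsumes the plain one; on a fan-out whose targets are
mutually unreachable nothing merges.

## Seriation

The initial order is Kahn's algorithm with an evidence-aware queue:
when a vertex is emitted, its newly ready successors are pushed to the
*front* of the queue in descending multiplicity of the connecting edge
bundle (ties by id), so well-supported adjacencies stay consecutive;
initial sources are processed in id order, which also fixes the order
of disconnected components deterministically.

The refinement minimizes the number τ of ordered triples violating the
Robinson condition under the dissimilarity d(i,k) = 1/|(i,k)| when a
direct edge exists (the direct edge always wins, even over a cheaper
path), else the minimum over directed paths of at most l edges of the
summed edge terms, else ∞. The path bound defaults to l = 10: d is a
meaningful co-linearity measure only at short range, and the bound
keeps the distance table sparse (O(|V|) entries on path-like graphs).
The "intermediate j" in the path case ranges over any vertex on a
bounded directed path, not over order ranks — the other reading would
make d depend on the very order being optimized. Because the Robinson
condition concerns a dissimilarity (symmetric by definition) while
directed-path distances are not, violations are counted under the
symmetrization d̂(u,v) = min(d(u,v), d(v,u)); only triples with all
three pairwise distances finite participate.

Moves are sibling swaps and move-before-sibling relocations (siblings:
two vertices sharing a predecessor, or two sources). Each candidate's
Δτ is evaluated exactly, over only the triples containing a moved
vertex, using rank overrides (a relocated vertex gets the fractional
rank target−½) so no full rank rebuild is needed. Each round executes
a maximal set of non-overlapping strictly improving moves, greedy by
most negative Δτ with ties to the leftmost affected rank; moves with
disjoint rank intervals cannot interact, so their deltas are additive
and τ is monotonically non-increasing. Descent stops when no improving
move exists or after `max_rounds` (default 100; descent almost always
exhausts much earlier).

## Coordinates

Global coordinates are assigned column-major in the final block order.
Within a row, each residue maps to its own column (gap columns are
skipped); negative-strand rows traverse their columns in reverse so
genomic order is preserved. Blocks are coordinatized in their native
orientation — the supergenome assigns no orientation to a block, so
column order within a block is left as aligned. Completion blocks
(unaligned gap fillers, added on request) do not enter graph
construction: their position is forced up to ties by their single
neighbor color, so they are inserted directly after their genomic
predecessor block (before their successor when no predecessor exists;
entirely unaligned contigs are appended at the end). This keeps the
optimization graph small without changing any attainable objective
value.

## Evaluation metrics

All metrics compare the final expanded block order against the
*initial* graph, i.e. the adjacencies of the input genomes; ranks are
expanded block positions, never contracted vertices. Reading-direction
classes use the rank sign only. Distance of a formerly adjacent pair
is |Δrank| − 1 (adjacent = 0), binned adjacent / 1–5 / > 5; feature
contiguity sums |Δrank| − 1 over consecutive covering blocks and bins
0 / 1–100 / > 100. A feature is *broken* when some consecutive pair of
its covering blocks appears in reverse order: the alternative reading
(broken = any non-adjacency) would contradict the separate distance
binning, under which features at small positive distance are still
"consistently represented". Edge retention rebuilds a betweenness
graph greedily — first all edges agreeing with the order, then, in
deterministic edge-key order, contradicting edges that create no
violated triple with already-retained same-colored edges — and reports
the retained fraction; the greedy second phase is an approximation,
not an optimum.

## Synthetic data

The generator models exactly what the ordering stages consume: block
coordinates, not sequence. An ancestral order of `n_blocks` blocks
(default 50, lengths uniform in 20–200 nt) shared by `n_genomes`
genomes (default 5) is mutated independently per genome by inversions
(segment reversed, strands flipped), transpositions, deletions, and
duplications (copies become fresh singleton blocks so injectivity is
preserved), then split into contigs. Segment lengths are uniform on
1..max(1, n/10) blocks. Scores are ℓ(B)·C(r,2)·`score_scale` so the
normalized score equals `score_scale` (default 1.0) and the score
filter can be exercised at any threshold. Row texts are runs of "A":
the pipeline never reads residues. The defaults (50 × 5, no
rearrangement, one contig) are the reference study condition for the
recovery checks; the seed fixes every output bit-exactly.

What the generator does **not** model: substitutions or indels inside
blocks, alignment errors, paralogy-driven misalignment, or
non-uniform rearrangement hotspots. Passing the recovery tests
therefore demonstrates the correctness of the combinatorial machinery
on clean and moderately rearranged inputs, not robustness to the
alignment artifacts that dominate real genome-wide MSAs — on real
data those artifacts are exactly what the curation filters exist to
suppress.

## Problem sizes and numerical notes

The oracle-equivalence study uses 200 random instances of 4–8 blocks
and 2–4 genomes: the exact enumeration is exercised at sizes where
8! = 40320 permutations fit comfortably in one vectorized pass, and
the optimality sub-claim (heuristic = optimum) is asserted on the
instances whose initial graph is acyclic, where topological sorting is
provably optimal for the full objective; on cyclic instances only the
lower-bound sanity holds. Property suites use 100 graphs each. All
floating-point distance comparisons are exact in the sense used: edge
terms are reciprocals of small integers and τ comparisons are integer
counts.

## Known limitations

* The mini-cycle support neighborhood and the propagation schedule are
  heuristic choices among several defensible ones; on adversarial
  complexes a different schedule can keep more edges.
* The sibling-swap move set cannot escape local minima that require
  relocating whole segments; no global search is attempted.
* Superbubble detection runs from every vertex each pass (quadratic in
  sparse practice); fine at the intended scales after contraction, but
  not tuned for multi-million-block alignments in this implementation.
* `read_maf` reports errors per block ordinal rather than per file
  line, a limitation of the underlying parser.
* Feature contiguity requires features on a single reference assembly;
  lift-over of arbitrary annotations is out of scope (join on the
  exported mapping table instead).
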