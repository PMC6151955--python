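# supercoord

Common coordinate systems for *supergenomes*: given a genome-wide
multiple sequence alignment (MAF), `supercoord` orders the alignment
blocks into a single linear coordinate system that stays as co-linear
as possible with **every** constituent genome, and maps each genome
position to a global supergenome coordinate.

A single reference genome is a poor coordinate system once many
species, rearrangements, and large insertions/deletions are involved.
`supercoord` instead treats the alignment itself as the coordinate
backbone: an MSA that is *complete* (every position covered),
*irredundant* (every position in at most one block), and *injective*
(at most one interval per assembly and block) admits a coordinate
function φ∘f mapping (assembly, contig, position) ↦ [1, n], where
n = Σ<sub>B</sub> ℓ(B) is the total column count. The only free choice —and
the computational problem — is the block order.

## The method

Ordering quality is measured by **betweenness**: for any three blocks
whose projections lie on one contig of some assembly 𝒢, the genomically
middle block must lie between the other two in the chosen order. The
objective

b(ρ) = Σ<sub>𝒢</sub> Σ<sub>i&lt;j&lt;k</sub> b<sub>ρ,𝒢</sub>(i, j, k)

counts the violated triples; minimizing it is NP-hard (it contains the
classical Betweenness Problem). `supercoord` therefore:

1. **curates** the input (drop blocks of ≤ 10 columns; drop blocks whose
   blastz sum-of-pairs score per column and row pair falls below −30;
   remove both copies of sequences overlapping by > 20 nt or nested in
   one another);
2. builds the **supergenome graph** — a directed multigraph on blocks
   whose edges, colored by assembly, record the predecessor relation
   along each contig (each color is a disjoint union of directed paths);
3. **simplifies** it to a fixed point with three local reductions that
   provably or heuristically fix the relative order of the merged
   blocks: source/sink contraction, superbubble contraction (a DAG is
   solved exactly by topological sorting), and greedy resolution of
   mini-cycle complexes (vertex pairs with edges both ways, grouped
   into vertex-disjoint maximal complexes);
4. breaks residual directed cycles with the **greedy feedback-arc-set**
   ordering of Eades–Lin–Smyth (edge multiplicities as weights);
5. **seriates** the final DAG: an evidence-sorted Kahn topological
   order, refined by a sibling-swap gradient descent on the number τ of
   triples violating the Robinson condition
   max{d(ρ(i),ρ(j)), d(ρ(j),ρ(k))} ≤ d(ρ(i),ρ(k)) under the
   graph dissimilarity d(i,k) = 1/|(i,k)| for edges and bounded-length
   shortest paths otherwise;
6. assigns **coordinates** column-major in the final block order and
   exports a BED-like per-interval mapping table.

An exact brute-force solver (vectorized permutation enumeration, ≤ 9
blocks) serves as an oracle, a rearrangement simulator provides inputs
with known ground truth, and the evaluation module implements the
standard quality metrics (block-distance distributions, order/adjacency
preservation, betweenness-graph edge retention, ORF/exon contiguity).

## Worked example

`examples/01_simulate_and_order.py` simulates 50 ancestral blocks in 5
genomes, inverts two segments of genome g5, and rebuilds the coordinate
system:

```
simulated 50 blocks, 5 genomes
  applied inversion to g5 at blocks (27, 32)
  applied inversion to g5 at blocks (11, 15)

graph: 50 vertices / 245 edges -> 1 / 0 after simplification (feedback weight removed: 0)
betweenness violations of the final order: 726
order preserved: 97.1%, adjacency preserved: 95.5%
  g1: order 100.0%, adjacency 100.0%
  g2: order 100.0%, adjacency 100.0%
  g3: order 100.0%, adjacency 100.0%
  g4: order 100.0%, adjacency 100.0%
  g5: order 85.7%, adjacency 77.6% (rearranged)
```

The four unrearranged genomes keep every successor relation in both
order and adjacency; only the inverted genome pays, at its inversion
breakpoints. The residual violation count is carried entirely by the
triples inside g5's inverted segments, which no total order can satisfy
simultaneously with the other four genomes.

`examples/03_betweenness_oracle.py` reproduces the classic four-block
counterexample to adjacency-only (Hamiltonian-path) ordering: two
unrelated inserts B2, B3 between shared flanks B1, B4. Exhaustive
enumeration of all 24 orders finds minimum cost 0, exactly 4 optimal
orders, and 2 solution classes up to reversal — B2 and B3 both between
the flanks, their mutual order free.

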