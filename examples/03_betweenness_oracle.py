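"""The four-block instance: why adjacency alone is not enough.

Two genomes carry unrelated inserts (B2, B3) between the shared flanks
B1 and B4.  The block adjacency graph is the path B2-B1-B4-B3, whose
Hamiltonian traversals put B1 or B4 in the middle -- biologically wrong.
The betweenness formulation recovers exactly the two correct solution
classes.
"""

from supercoord import betweenness_cost, exact_betweenness_order
from supercoord.model import MSA, AlignmentBlock, SequenceInterval


def iv(g, c, s, e):
    return SequenceInterval(g, c, s, e)


msa = MSA([
    AlignmentBlock("B1", (iv("g1", "c", 0, 20), iv("g2", "c", 0, 20),
                          iv("g3", "c", 0, 20)), 20),
    AlignmentBlock("B2", (iv("g2", "c", 20, 40),), 20),
    AlignmentBlock("B3", (iv("g3", "c", 20, 40),), 20),
    AlignmentBlock("B4", (iv("g1", "c", 20, 40), iv("g2", "c", 40, 60),
                          iv("g3", "c", 40, 60)), 20),
])

order, cost, optima = exact_betweenness_order(msa, return_optima=True)
print(f"exhaustive search over 24 orders: minimum cost {cost}")
print(f"optimal orders ({len(optima)}):")
for o in optima:
    print("  " + " < ".join(o.sequence))

classes = {frozenset({o.sequence, o.reversed().sequence}) for o in optima}
print(f"solution classes up to reversal: {len(classes)}")

bad = betweenness_cost(order.reversed(), msa)
print(f"cost of the reversed optimum (symmetry check): {bad}")

# Both B2 and B3 must lie between B1 and B4; their mutual order is free,
# giving 2 classes x 2 reading directions = 4 optimal permutations.
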