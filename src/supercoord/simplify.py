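"""Graph simplifiers: source/sink contraction, superbubbles, mini-cycles.

Three local reductions shrink the supergenome graph while fixing the
relative order of the merged blocks:

* a source with a single distinct successor is placed immediately
  before it (sinks symmetrically after their single predecessor);
* a superbubble (single-entrance single-exit acyclic subgraph whose
  interior is isolated from the rest of the graph) is replaced by one
  vertex whose internal order is an evidence-sorted topological order;
* mini-cycles (vertex pairs with edges both ways) are grouped into
  maximal vertex-sharing complexes and resolved greedily by dropping
  the less supported direction of each adjacency.

``simplify_to_fixed_point`` iterates all three until nothing changes;
``dag_simplify`` is the generalized source/sink pass used once the
graph is acyclic.

All tie-breaks are lexicographic on vertex ids: the whole pipeline is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import SupergenomeGraph

__all__ = [
    "Superbubble",
    "MiniCycleComplex",
    "contract_sources_sinks",
    "find_superbubbles",
    "contract_superbubble",
    "find_minicycle_complexes",
    "resolve_complex",
    "simplify_to_fixed_point",
    "dag_simplify",
]


@dataclass(frozen=True)
class Superbubble:
    entrance: str
    exit: str
    interior: frozenset[str]

    @property
    def vertices(self) -> frozenset[str]:
        return self.interior | {self.entrance, self.exit}


@dataclass(frozen=True)
class MiniCycleComplex:
    """A maximal connected set of mini-cycles (pairs linked both ways)."""

    cycles: frozenset[frozenset[str]]

    @property
    def vertices(self) -> frozenset[str]:
        out: set[str] = set()
        for pair in self.cycles:
            out |= pair
        return frozenset(out)


# ---------------------------------------------------------------------------
# source / sink contraction


def contract_sources_sinks(
    graph: SupergenomeGraph,
) -> tuple[SupergenomeGraph, int]:
    """Merge every source/sink with its unique neighbor, repeatedly.

    A source s with exactly one distinct successor t is contracted to a
    vertex with internal order [s, t]; a sink s with one distinct
    predecessor t to [t, s].  Isolated vertices are untouched.  Returns
    the simplified graph and the number of contractions.
    """
    g = graph.copy()
    count = 0
    changed = True
    while changed:
        changed = False
        for v in sorted(g.members):
            if v not in g.members:
                continue
            ins, outs = g.in_neighbors(v), g.out_neighbors(v)
            if not ins and len(outs) == 1:
                (t,) = outs
                g.contract([v, t], new_id=t)
                count += 1
                changed = True
            elif not outs and len(ins) == 1:
                (t,) = ins
                g.contract([t, v], new_id=t)
                count += 1
                changed = True
    return g, count


# ---------------------------------------------------------------------------
# superbubbles


def _bubble_from(g: SupergenomeGraph, s: str) -> Superbubble | None:
    """Minimal superbubble with entrance s, or None.

    Standard forward search on the color-blind simple digraph: grow the
    visited set from s, pushing a vertex only once all its parents are
    visited; the bubble closes when exactly one frontier vertex remains
    and nothing else is pending.
    """
    seen = {s}  # seen but not yet visited
    visited: set[str] = set()
    stack = [s]
    while stack:
        v = stack.pop()
        visited.add(v)
        seen.discard(v)
        children = g.out_neighbors(v)
        if not children:
            return None  # tip: dead end inside the candidate bubble
        for u in sorted(children):
            if u == s:
                return None  # cycle back to the entrance
            seen.add(u)
        for u in sorted(seen):
            if u not in stack and g.in_neighbors(u) <= visited:
                stack.append(u)
        if len(stack) == 1 and seen == {stack[0]}:
            t = stack[0]
            if s in g.out_neighbors(t):
                return None
            interior = frozenset(visited - {s})
            return Superbubble(s, t, interior)
    return None


def find_superbubbles(graph: SupergenomeGraph) -> list[Superbubble]:
    """All minimal superbubbles, innermost (smallest) first.

    Trivial motifs are excluded: a plain edge u->v with empty interior
    counts only when at least two parallel edges run from u to v
    (otherwise the source/sink rule covers it).  Candidate interiors
    containing directed cycles are rejected by the search itself.
    """
    out = []
    for s in sorted(graph.members):
        if not graph.out_neighbors(s):
            continue
        b = _bubble_from(graph, s)
        if b is None:
            continue
        if not b.interior and len(graph.edges_between(s, b.exit)) < 2 \
                and graph.bundle_mult(s, b.exit) < 2:
            continue
        out.append(b)
    out.sort(key=lambda b: (len(b.interior), b.entrance))
    return out


def contract_superbubble(
    graph: SupergenomeGraph, bubble: Superbubble
) -> SupergenomeGraph:
    """Replace a superbubble by one vertex in topologically sorted order.

    The internal order is the evidence-sorted topological order of the
    induced subgraph (ties by vertex id), so nested contractions expand
    to the same block sequence as contracting the flattened bubble.
    """
    from .seriation import evidence_topological_order

    g = graph.copy()
    for v in bubble.vertices:
        if v not in g.members:
            raise ValueError(f"bubble vertex {v!r} not in graph")
    sub_order = evidence_topological_order(g, restrict=set(bubble.vertices))
    g.contract(sub_order, new_id=bubble.entrance)
    return g


# ---------------------------------------------------------------------------
# mini-cycles


def find_minicycle_complexes(graph: SupergenomeGraph) -> list[MiniCycleComplex]:
    """Partition all mini-cycles into maximal vertex-sharing complexes."""
    pairs = set()
    for (t, h, _c, _g) in graph.edge_keys():
        if t < h and graph.has_edge(h, t):
            pairs.add(frozenset((t, h)))
    # union-find over shared vertices
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        for v in p:
            parent.setdefault(v, v)
        a, b = sorted(p)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[str, set[frozenset[str]]] = {}
    for p in pairs:
        root = find(sorted(p)[0])
        groups.setdefault(root, set()).add(p)
    return [
        MiniCycleComplex(frozenset(cycles))
        for _root, cycles in sorted(groups.items())
    ]


def _adjacency_support(g: SupergenomeGraph, pair: frozenset[str]):
    v, w = sorted(pair)
    fwd = g.bundle_mult(v, w)
    bwd = g.bundle_mult(w, v)
    mult = fwd + bwd
    bias = max(fwd, bwd) / mult if mult else 0.0
    return mult, bias, fwd, bwd


def _closes_cycle(decided: dict, tail: str, head: str) -> bool:
    """Would directing tail->head close a cycle among decided edges?"""
    succ: dict[str, set[str]] = {}
    for (t, h) in decided.values():
        succ.setdefault(t, set()).add(h)
    stack = [head]
    seen = {head}
    while stack:
        u = stack.pop()
        if u == tail:
            return True
        for w in succ.get(u, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def resolve_complex(
    graph: SupergenomeGraph, complex_: MiniCycleComplex
) -> SupergenomeGraph:
    """Orient every adjacency of a mini-cycle complex and drop the losers.

    Adjacencies are decided in descending support (multiplicity, then
    direction bias), preferring ones incident to already-decided
    vertices so the chosen orientation propagates.  An adjacency with no
    majority direction adopts the orientation pointing away from a
    previously decided endpoint; a direction that would close a
    directed cycle among the decided edges is replaced by its reverse.
    Finally all edges contradicting the decisions are removed.  Cycles
    not inside the complex are left intact.
    """
    g = graph.copy()
    undecided = set(complex_.cycles)
    decided: dict[frozenset[str], tuple[str, str]] = {}
    decided_vertices: set[str] = set()

    def support_key(pair: frozenset[str]):
        mult, bias, _f, _b = _adjacency_support(g, pair)
        return (-mult, -bias, tuple(sorted(pair)))

    while undecided:
        touching = [p for p in undecided if p & decided_vertices]
        pool = touching if touching else undecided
        pair = min(pool, key=support_key)
        v, w = sorted(pair)
        _mult, _bias, fwd, bwd = _adjacency_support(g, pair)
        if fwd > bwd:
            direction = (v, w)
        elif bwd > fwd:
            direction = (w, v)
        else:
            inside = pair & decided_vertices
            if len(inside) == 1:
                # point away from the already-placed vertex
                (anchor,) = inside
                other = w if anchor == v else v
                direction = (anchor, other)
            else:
                direction = (v, w)
        if _closes_cycle(decided, *direction):
            direction = (direction[1], direction[0])
        decided[pair] = direction
        decided_vertices |= pair
        undecided.discard(pair)

    for pair, (tail, head) in decided.items():
        for key in list(g.edge_keys()):
            if key[0] == head and key[1] == tail:
                g.remove_edge(key)
    return g


# ---------------------------------------------------------------------------
# fixed-point scheduler


def _inner_pass(g: SupergenomeGraph) -> tuple[SupergenomeGraph, int]:
    """Source/sink + superbubble contraction to a joint fixed point."""
    total = 0
    while True:
        g, n1 = contract_sources_sinks(g)
        n2 = 0
        while True:
            bubbles = find_superbubbles(g)
            if not bubbles:
                break
            g = contract_superbubble(g, bubbles[0])
            n2 += 1
        total += n1 + n2
        if n1 == 0 and n2 == 0:
            return g, total


def simplify_to_fixed_point(graph: SupergenomeGraph) -> SupergenomeGraph:
    """Iterate all three simplifiers until the mini-cycle pass is a no-op.

    Inner loop: source/sink and superbubble contraction to a fixed
    point; then one mini-cycle pass over all current complexes; the
    outer loop repeats while the mini-cycle pass removed any edge.
    """
    g = graph.copy()
    while True:
        g, _ = _inner_pass(g)
        complexes = find_minicycle_complexes(g)
        if not complexes:
            return g
        before = g.n_edges
        for c in complexes:
            g = resolve_complex(g, c)
        if g.n_edges == before:
            return g


def dag_simplify(graph: SupergenomeGraph) -> SupergenomeGraph:
    """Generalized source/sink contraction for acyclic graphs.

    A source s whose successor v reaches every other successor of s is
    placed immediately before v; a sink t whose predecessor v is
    reached by every other predecessor of t is placed immediately after
    v.  Iterated to a fixed point.
    """
    g = graph.copy()
    if not g.is_acyclic():
        raise ValueError("dag_simplify requires an acyclic graph")
    changed = True
    while changed:
        changed = False
        for s in sorted(g.members):
            if s not in g.members:
                continue
            ins, outs = g.in_neighbors(s), g.out_neighbors(s)
            if not ins and outs:
                for v in sorted(outs):
                    reach = g.reachable_from(v)
                    if all(w in reach for w in outs if w != v):
                        g.contract([s, v], new_id=v)
                        changed = True
                        break
            elif not outs and ins:
                for v in sorted(ins):
                    if all(v in g.reachable_from(w) for w in ins if w != v):
                        g.contract([v, s], new_id=v)
                        changed = True
                        break
    return g
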