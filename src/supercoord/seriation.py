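"""Seriation of the simplified DAG into the final total order.

Two steps produce the coordinate order.  First an evidence-sorted
topological order (a modified Kahn's algorithm) places strongly
supported adjacencies consecutively.  Second, a discrete gradient
descent on sibling swaps minimizes the number tau of ordered triples
violating the Robinson condition

    max{ d(rho(i), rho(j)), d(rho(j), rho(k)) } <= d(rho(i), rho(k))

for ranks i < j < k, under the graph-derived dissimilarity

    d(i, k) = 1 / |(i, k)|                  if an edge (i, k) exists,
            = min over paths of <= l edges  otherwise,
            = infinity                      if no such path exists,

where |(i, k)| is the number of parallel edges from i to k.  The path
bound l (default 10) keeps the distance table sparse; d is a useful
co-linearity measure only at short range.  Since the Robinson condition
concerns a dissimilarity, the directed table is symmetrized as
d^(u, v) = min(d(u, v), d(v, u)) when counting violations.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

from .graph import BlockOrder, SupergenomeGraph

__all__ = [
    "evidence_topological_order",
    "initial_topological_order",
    "DistanceTable",
    "block_distance",
    "distance_table",
    "robinson_tau",
    "optimize_order",
]


def evidence_topological_order(
    graph: SupergenomeGraph, restrict: set[str] | None = None
) -> list[str]:
    """Kahn's algorithm with successors prioritized by adjacency evidence.

    When a vertex is emitted, its newly ready successors are placed at
    the front of the queue in descending multiplicity of the connecting
    edge bundle (ties by vertex id), so well-supported adjacencies stay
    consecutive.  Initial sources are processed in id order.  Raises on
    cycles.
    """
    verts = set(graph.members) if restrict is None else set(restrict)
    indeg = {
        v: sum(1 for u in graph.in_neighbors(v) if u in verts) for v in verts
    }
    ready: deque[str] = deque(sorted(v for v in verts if indeg[v] == 0))
    out: list[str] = []
    while ready:
        v = ready.popleft()
        out.append(v)
        newly: list[str] = []
        for u in graph.out_neighbors(v):
            if u not in verts:
                continue
            indeg[u] -= 1
            if indeg[u] == 0:
                newly.append(u)
        newly.sort(key=lambda u: (-graph.bundle_mult(v, u), u))
        ready.extendleft(reversed(newly))
    if len(out) != len(verts):
        raise ValueError("graph contains a directed cycle; run mfas first")
    return out


def initial_topological_order(dag: SupergenomeGraph) -> BlockOrder:
    """The seriation starting point over (contracted) vertices."""
    return BlockOrder(evidence_topological_order(dag))


class DistanceTable:
    """Sparse directed distances d(i, k); missing entries mean infinity."""

    def __init__(self, d: dict[tuple[str, str], float], l: int):
        self.d = d
        self.l = l
        self._partners: dict[str, set[str]] = {}
        for (u, v) in d:
            self._partners.setdefault(u, set()).add(v)
            self._partners.setdefault(v, set()).add(u)

    def directed(self, u: str, v: str) -> float:
        return self.d.get((u, v), math.inf)

    def sym(self, u: str, v: str) -> float:
        """Symmetrized dissimilarity min(d(u,v), d(v,u))."""
        return min(
            self.d.get((u, v), math.inf), self.d.get((v, u), math.inf)
        )

    def partners(self, u: str) -> set[str]:
        """Vertices at finite distance from u in either direction."""
        return self._partners.get(u, set())


def distance_table(dag: SupergenomeGraph, l: int = 10) -> DistanceTable:
    """All pairwise distances realized by directed paths of <= l edges.

    Path cost is the sum of 1/multiplicity over its edge bundles; a
    direct edge always contributes exactly 1/multiplicity even when a
    longer path would be cheaper.
    """
    d: dict[tuple[str, str], float] = {}
    for s in dag.members:
        best: dict[str, float] = {}
        frontier = {s: 0.0}
        for _hop in range(l):
            nxt: dict[str, float] = {}
            for v, cost in frontier.items():
                for w in dag.out_neighbors(v):
                    cand = cost + 1.0 / dag.bundle_mult(v, w)
                    if cand < best.get(w, math.inf) and cand < nxt.get(w, math.inf):
                        nxt[w] = cand
            for w, cost in nxt.items():
                if cost < best.get(w, math.inf):
                    best[w] = cost
            frontier = nxt
            if not frontier:
                break
        for w, cost in best.items():
            if w != s:
                d[(s, w)] = cost
    # direct edges override any path minimum
    seen_pairs = set()
    for (t, h, _c, _g) in dag.edge_keys():
        if (t, h) not in seen_pairs:
            seen_pairs.add((t, h))
            d[(t, h)] = 1.0 / dag.bundle_mult(t, h)
    return DistanceTable(d, l)


def block_distance(
    dag: SupergenomeGraph, i: str, k: str, l: int = 10
) -> float:
    """Single-pair distance d(i, k); infinity if k is out of reach."""
    if dag.has_edge(i, k):
        return 1.0 / dag.bundle_mult(i, k)
    best = math.inf
    frontier = {i: 0.0}
    seen: dict[str, float] = {}
    for _hop in range(l):
        nxt: dict[str, float] = {}
        for v, cost in frontier.items():
            for w in dag.out_neighbors(v):
                cand = cost + 1.0 / dag.bundle_mult(v, w)
                if cand < seen.get(w, math.inf):
                    seen[w] = cand
                    nxt[w] = cand
        frontier = nxt
        if not frontier:
            break
    return seen.get(k, best)


def _finite_triples(order: BlockOrder, distances: DistanceTable):
    """All id triples with pairwise finite symmetric distances."""
    triples: set[tuple[str, str, str]] = set()
    for u in order:
        part = [p for p in distances.partners(u) if p in order]
        for a, b in itertools.combinations(sorted(part), 2):
            if math.isfinite(distances.sym(a, b)):
                t = tuple(sorted((u, a, b)))
                triples.add(t)  # type: ignore[arg-type]
    return triples


def _violated(
    t: tuple[str, str, str],
    distances: DistanceTable,
    rank: dict[str, float],
) -> bool:
    a, b, c = sorted(t, key=lambda v: rank[v])
    return max(distances.sym(a, b), distances.sym(b, c)) > distances.sym(a, c)


def robinson_tau(order: BlockOrder, distances: DistanceTable) -> int:
    """Count of rank triples i<j<k violating the Robinson condition.

    Only triples whose three pairwise (symmetrized) distances are all
    finite are considered; with a bounded path length the distance
    table is sparse and the count stays near-linear in practice.
    """
    rank = dict(order.ranks)
    return sum(
        1
        for t in _finite_triples(order, distances)
        if _violated(t, distances, rank)
    )


def _siblings(dag: SupergenomeGraph, verts: set[str]) -> set[frozenset[str]]:
    """Pairs sharing a predecessor, plus all pairs of sources."""
    pairs: set[frozenset[str]] = set()
    for p in dag.members:
        kids = sorted(k for k in dag.out_neighbors(p) if k in verts)
        for a, b in itertools.combinations(kids, 2):
            pairs.add(frozenset((a, b)))
    sources = sorted(
        v for v in verts if not (dag.in_neighbors(v) & verts)
    )
    for a, b in itertools.combinations(sources, 2):
        pairs.add(frozenset((a, b)))
    return pairs


def optimize_order(
    order: BlockOrder,
    dag: SupergenomeGraph,
    distances: DistanceTable,
    max_rounds: int = 100,
    return_trace: bool = False,
):
    """Sibling-swap gradient descent on tau.

    Per round, every sibling swap and move-before-sibling relocation is
    scored by its exact tau change (evaluated only over triples
    containing a moved vertex); a maximal set of non-overlapping
    strictly improving moves (greedy by most negative delta, ties by
    leftmost affected rank) is executed.  Stops when no improving move
    exists or after ``max_rounds``.  tau never increases.

    With ``return_trace`` the incrementally tracked tau after each
    round (starting value first) is returned alongside the order.
    """
    seq = list(order.sequence)
    tau_inc = robinson_tau(order, distances)
    trace = [tau_inc]
    verts = set(seq)
    sib = _siblings(dag, verts)
    triples = _finite_triples(order, distances)
    by_vertex: dict[str, list[tuple[str, str, str]]] = {v: [] for v in seq}
    for t in triples:
        for v in t:
            by_vertex[v].append(t)

    for _round in range(max_rounds):
        rank: dict[str, float] = {v: i for i, v in enumerate(seq)}

        def delta_for(moved: tuple[str, ...], override: dict[str, float]) -> int:
            affected = {t for v in moved for t in by_vertex[v]}
            new_rank = dict(rank)
            new_rank.update(override)
            change = 0
            for t in affected:
                change += _violated(t, distances, new_rank) - _violated(
                    t, distances, rank
                )
            return change

        candidates: list[tuple[int, int, int, tuple]] = []
        for pair in sib:
            u, v = sorted(pair, key=lambda x: rank[x])
            ru, rv = int(rank[u]), int(rank[v])
            moves = [
                (("swap", u, v), (u, v), {u: float(rv), v: float(ru)}),
                (("before", u, v), (u,), {u: rv - 0.5}),
                (("before", v, u), (v,), {v: ru - 0.5}),
            ]
            for descr, moved, override in moves:
                dlt = delta_for(moved, override)
                if dlt < 0:
                    candidates.append((dlt, ru, rv, descr))
        if not candidates:
            break
        candidates.sort()
        taken: list[tuple[int, int]] = []
        chosen = []
        for dlt, ru, rv, descr in candidates:
            lo, hi = ru, rv
            if descr[0] == "before":
                # moving x to just before y affects ranks between them
                x, y = descr[1], descr[2]
                lo, hi = sorted((int(rank[x]), int(rank[y])))
            if any(not (hi < a or b < lo) for a, b in taken):
                continue
            taken.append((lo, hi))
            chosen.append(descr)
        executed_delta = 0
        for dlt, ru, rv, descr in candidates:
            if descr in chosen:
                executed_delta += dlt
        for descr in chosen:
            if descr[0] == "swap":
                _, u, v = descr
                iu, iv = seq.index(u), seq.index(v)
                seq[iu], seq[iv] = seq[iv], seq[iu]
            else:
                _, x, y = descr
                seq.remove(x)
                seq.insert(seq.index(y), x)
        tau_inc += executed_delta
        trace.append(tau_inc)
    out = BlockOrder(seq)
    if return_trace:
        return out, trace
    return out
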