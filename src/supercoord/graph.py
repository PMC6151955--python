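"""The supergenome graph, betweenness cost, and the exact solver.

The supergenome graph is a directed, edge-colored multigraph whose
vertices are alignment blocks and whose edges record the predecessor
relation of block projections along each assembly (the edge color) and
contig.  Restricted to one color the graph is a disjoint union of
directed paths, one per contig.

Block ordering quality is measured by the number of violated
betweenness constraints: for every assembly, any three blocks on one
contig demand that the genomically middle one also lies between the
other two in the chosen total order.  Minimizing that count is NP-hard,
hence the exact solver enumerates permutations and is capped at small
instances; it serves as the oracle for the heuristic pipeline.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import MSA

__all__ = [
    "SupergenomeGraph",
    "BlockOrder",
    "BetweennessTriple",
    "build_graph",
    "betweenness_triples",
    "betweenness_cost",
    "exact_betweenness_order",
    "color_paths",
]

EdgeKey = tuple[str, str, str, str]  # (tail, head, color, contig)


class BlockOrder:
    """A total order of block (or vertex) ids: rho as an explicit list."""

    __slots__ = ("sequence", "_rank")

    def __init__(self, sequence):
        self.sequence: tuple[str, ...] = tuple(sequence)
        self._rank = {v: i for i, v in enumerate(self.sequence)}
        if len(self._rank) != len(self.sequence):
            raise ValueError("order contains duplicate ids")

    def rank(self, v: str) -> int:
        return self._rank[v]

    @property
    def ranks(self) -> dict[str, int]:
        return self._rank

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)

    def __contains__(self, v) -> bool:
        return v in self._rank

    def __eq__(self, other) -> bool:
        return isinstance(other, BlockOrder) and self.sequence == other.sequence

    def __hash__(self) -> int:
        return hash(self.sequence)

    def __repr__(self) -> str:
        return f"BlockOrder({list(self.sequence)!r})"

    def reversed(self) -> "BlockOrder":
        return BlockOrder(reversed(self.sequence))


@dataclass(frozen=True)
class BetweennessTriple:
    """(left, middle, right) with the witnessing color; (i,j,k)==(k,j,i)."""

    left: str
    middle: str
    right: str
    color: str

    @staticmethod
    def canonical(i: str, j: str, k: str, color: str) -> "BetweennessTriple":
        a, b = sorted((i, k))
        return BetweennessTriple(a, j, b, color)


class SupergenomeGraph:
    """Directed edge-colored multigraph over (possibly contracted) vertices.

    Each vertex carries an ordered tuple of member block ids; a plain
    block vertex has itself as sole member.  Edges are stored as a
    multiset keyed by (tail, head, color, contig).  The graph also keeps
    an occupancy table per (color, contig): the genomic vertex order,
    maintained through contractions, from which color paths are derived.
    """

    def __init__(self):
        self.members: dict[str, tuple[str, ...]] = {}
        self._edges: dict[EdgeKey, int] = {}
        self._out: dict[str, dict[str, Counter]] = {}
        self._in: dict[str, dict[str, Counter]] = {}
        self._occupancy: dict[tuple[str, str], list[str]] = {}

    # -- construction ---------------------------------------------------
    def add_vertex(self, v: str, members: tuple[str, ...] | None = None):
        if v in self.members:
            raise ValueError(f"vertex {v!r} already present")
        self.members[v] = members if members is not None else (v,)
        self._out.setdefault(v, {})
        self._in.setdefault(v, {})

    def add_edge(self, tail: str, head: str, color: str, contig: str, mult: int = 1):
        if tail == head:
            raise ValueError(f"self-loop on {tail!r}")
        for v in (tail, head):
            if v not in self.members:
                raise KeyError(f"unknown vertex {v!r}")
        key = (tail, head, color, contig)
        self._edges[key] = self._edges.get(key, 0) + mult
        self._out[tail].setdefault(head, Counter())[(color, contig)] += mult
        self._in[head].setdefault(tail, Counter())[(color, contig)] += mult

    def remove_edge(self, key: EdgeKey):
        tail, head, color, contig = key
        mult = self._edges.pop(key)
        bundle = self._out[tail][head]
        del bundle[(color, contig)]
        if not bundle:
            del self._out[tail][head]
        bundle = self._in[head][tail]
        del bundle[(color, contig)]
        if not bundle:
            del self._in[head][tail]
        return mult

    # -- queries --------------------------------------------------------
    @property
    def vertices(self) -> list[str]:
        return list(self.members)

    @property
    def n_vertices(self) -> int:
        return len(self.members)

    @property
    def n_edges(self) -> int:
        """Total edge multiplicity."""
        return sum(self._edges.values())

    def edge_items(self):
        return self._edges.items()

    def edge_keys(self):
        return list(self._edges)

    def has_edge(self, tail: str, head: str) -> bool:
        return head in self._out.get(tail, {})

    def edges_between(self, tail: str, head: str) -> Counter:
        return self._out.get(tail, {}).get(head, Counter())

    def bundle_mult(self, tail: str, head: str) -> int:
        return sum(self.edges_between(tail, head).values())

    def out_neighbors(self, v: str) -> set[str]:
        return set(self._out.get(v, {}))

    def in_neighbors(self, v: str) -> set[str]:
        return set(self._in.get(v, {}))

    def colors(self) -> set[str]:
        return {c for (_, _, c, _) in self._edges}

    def expand(self, vertex_order) -> list[str]:
        """Flatten a vertex order into the underlying block order."""
        return [b for v in vertex_order for b in self.members[v]]

    def copy(self) -> "SupergenomeGraph":
        g = SupergenomeGraph()
        g.members = dict(self.members)
        g._edges = dict(self._edges)
        g._out = {v: {w: Counter(c) for w, c in d.items()} for v, d in self._out.items()}
        g._in = {v: {w: Counter(c) for w, c in d.items()} for v, d in self._in.items()}
        g._occupancy = {k: list(v) for k, v in self._occupancy.items()}
        return g

    def is_acyclic(self) -> bool:
        return len(self._kahn_count()) == self.n_vertices

    def _kahn_count(self) -> list[str]:
        indeg = {v: len(self._in[v]) for v in self.members}
        ready = [v for v, d in indeg.items() if d == 0]
        out = []
        while ready:
            v = ready.pop()
            out.append(v)
            for w in self._out[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    ready.append(w)
        return out

    def reachable_from(self, v: str) -> set[str]:
        seen = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for w in self._out[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    # -- contraction ----------------------------------------------------
    def contract(self, internal_order: list[str], new_id: str | None = None) -> str:
        """Merge the vertices of ``internal_order`` into one vertex.

        The merged vertex's member list concatenates the members in the
        given order.  Edges between group members disappear; external
        edges are re-attached (parallel edges preserved).  Returns the
        id of the merged vertex (default: the first of the group).
        """
        group = set(internal_order)
        if len(group) != len(internal_order):
            raise ValueError("internal order repeats a vertex")
        if new_id is None:
            new_id = internal_order[0]
        if new_id not in group and new_id in self.members:
            raise ValueError(f"new id {new_id!r} collides with existing vertex")
        members_new = tuple(
            b for v in internal_order for b in self.members[v]
        )
        moved = [
            (key, mult)
            for key, mult in self._edges.items()
            if key[0] in group or key[1] in group
        ]
        for key, _ in moved:
            self.remove_edge(key)
        for v in group:
            del self.members[v]
            del self._out[v]
            del self._in[v]
        self.add_vertex(new_id, members_new)
        for (t, h, c, g), mult in moved:
            nt = new_id if t in group else t
            nh = new_id if h in group else h
            if nt != nh:
                self.add_edge(nt, nh, c, g, mult)
        for key, lst in self._occupancy.items():
            new_lst: list[str] = []
            for v in lst:
                nv = new_id if v in group else v
                if not new_lst or new_lst[-1] != nv:
                    new_lst.append(nv)
            self._occupancy[key] = new_lst
        return new_id

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        """Assert the per-color path structure (union of directed paths)."""
        per_key: dict[tuple[str, str], dict[str, str]] = {}
        indeg: dict[tuple[str, str], Counter] = {}
        for (t, h, c, g), mult in self._edges.items():
            succ = per_key.setdefault((c, g), {})
            if t in succ:
                raise ValueError(
                    f"color {c}/{g}: vertex {t} has two successors"
                )
            succ[t] = h
            d = indeg.setdefault((c, g), Counter())
            d[h] += 1
            if d[h] > 1:
                raise ValueError(
                    f"color {c}/{g}: vertex {h} has two predecessors"
                )
        # acyclicity per color+contig: follow each path
        for key, succ in per_key.items():
            heads = set(succ.values())
            starts = [v for v in succ if v not in heads]
            visited = set()
            for s in starts:
                v = s
                while v in succ:
                    if v in visited:
                        raise ValueError(f"color {key}: cycle detected")
                    visited.add(v)
                    v = succ[v]
            if len(visited) != len(succ):
                raise ValueError(f"color {key}: cycle detected")

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for v, mem in self.members.items():
            g.add_node(v, members=",".join(mem))
        for (t, h, c, ctg), mult in self._edges.items():
            for _ in range(mult):
                g.add_edge(t, h, color=c, contig=ctg)
        return g


def build_graph(msa: MSA) -> SupergenomeGraph:
    """Construct the supergenome graph of a filtered MSA.

    Intervals are sorted per assembly and contig; each consecutive pair
    of (distinct) blocks contributes one edge colored by the assembly.
    Ties in start position cannot occur after filtering and raise.
    """
    g = SupergenomeGraph()
    for b in msa.blocks:
        g.add_vertex(b.id)
    for (assembly, contig), pairs in sorted(msa.intervals_by_contig().items()):
        prev_start = None
        seq: list[str] = []
        for iv, bid in pairs:
            if prev_start is not None and iv.start == prev_start:
                raise ValueError(
                    f"{assembly}.{contig}: two intervals start at "
                    f"{iv.start}; filter the MSA first"
                )
            prev_start = iv.start
            if not seq or seq[-1] != bid:
                seq.append(bid)
        g._occupancy[(assembly, contig)] = list(seq)
        for a, b_ in zip(seq, seq[1:]):
            if a != b_:
                g.add_edge(a, b_, assembly, contig)
    return g


def betweenness_triples(graph: SupergenomeGraph) -> set[BetweennessTriple]:
    """The collection C(Gamma^) of graph-local betweenness triples.

    Edges are read undirected; a triple (i, j, k) arises whenever two
    edges {i,j} and {j,k} of the same color meet at j.
    """
    nbrs: dict[tuple[str, str], set[str]] = {}
    for (t, h, c, _), _mult in graph.edge_items():
        nbrs.setdefault((t, c), set()).add(h)
        nbrs.setdefault((h, c), set()).add(t)
    out: set[BetweennessTriple] = set()
    for (j, color), around in nbrs.items():
        for i, k in itertools.combinations(sorted(around), 2):
            out.add(BetweennessTriple.canonical(i, j, k, color))
    return out


def _contig_orders(msa: MSA, restrict: set[str] | None = None):
    """Genomic block order per (assembly, contig), duplicates dropped."""
    for (assembly, contig), pairs in sorted(msa.intervals_by_contig().items()):
        seen: Counter = Counter(bid for _, bid in pairs)
        ordered = [
            bid
            for _, bid in pairs
            if seen[bid] == 1 and (restrict is None or bid in restrict)
        ]
        if len(ordered) >= 3:
            yield (assembly, contig), ordered


def betweenness_cost(
    order: BlockOrder,
    msa: MSA,
    mode: str = "full",
    graph: SupergenomeGraph | None = None,
) -> int:
    """Number of betweenness violations b(rho) of a block order.

    ``mode="full"`` sums over all triples of blocks that co-occur on one
    contig (the exact objective; cubic).  ``mode="graph"`` restricts the
    sum to the graph-local triples C(Gamma^) and needs ``graph``.
    """
    rank = order.ranks
    if mode == "graph":
        if graph is None:
            raise ValueError("graph mode requires the supergenome graph")
        total = 0
        for t in betweenness_triples(graph):
            ri, rj, rk = rank[t.left], rank[t.middle], rank[t.right]
            if not (ri < rj < rk or rk < rj < ri):
                total += 1
        return total
    if mode != "full":
        raise ValueError(f"unknown mode {mode!r}")
    total = 0
    for _key, ordered in _contig_orders(msa, set(rank)):
        for ia, im, ib in itertools.combinations(ordered, 3):
            ri, rj, rk = rank[ia], rank[im], rank[ib]
            if not (ri < rj < rk or rk < rj < ri):
                total += 1
    return total


def exact_betweenness_order(
    msa: MSA, max_blocks: int = 9, return_optima: bool = False
):
    """Brute-force minimizer of the full betweenness cost.

    Enumerates all permutations of the block set (vectorized over
    numpy), so it refuses instances with more than ``max_blocks``
    blocks.  Ties are broken by lexicographic order of the id sequence.
    With ``return_optima`` the full list of optimal orders is returned
    as a third element.
    """
    bids = sorted({b.id for b in msa.blocks})
    n = len(bids)
    if n > max_blocks:
        raise ValueError(
            f"instance has {n} blocks; exact enumeration is capped at "
            f"{max_blocks}"
        )
    if n == 0:
        empty = BlockOrder(())
        return (empty, 0, [empty]) if return_optima else (empty, 0)
    index = {bid: i for i, bid in enumerate(bids)}
    triples: list[tuple[int, int, int]] = []
    for _key, ordered in _contig_orders(msa):
        for ia, im, ib in itertools.combinations(ordered, 3):
            triples.append((index[ia], index[im], index[ib]))
    perms = np.array(
        list(itertools.permutations(range(n))), dtype=np.int8
    )  # rows in lexicographic order of id sequences
    nperm = perms.shape[0]
    pos = np.empty((nperm, n), dtype=np.int8)
    pos[np.arange(nperm)[:, None], perms] = np.arange(n, dtype=np.int8)[None, :]
    cost = np.zeros(nperm, dtype=np.int32)
    for ia, im, ib in triples:
        a, m, b = pos[:, ia], pos[:, im], pos[:, ib]
        ok = ((a < m) & (m < b)) | ((b < m) & (m < a))
        cost += ~ok
    best = int(cost.min())
    opt_idx = np.flatnonzero(cost == best)
    best_order = BlockOrder(bids[i] for i in perms[opt_idx[0]])
    if return_optima:
        optima = [BlockOrder(bids[i] for i in perms[j]) for j in opt_idx]
        return best_order, best, optima
    return best_order, best


def color_paths(graph: SupergenomeGraph, assembly: str) -> list[list[str]]:
    """Current directed paths of one color, one (or more) per contig.

    Derived from the occupancy table: a contig's vertex sequence is
    split wherever the connecting edge of this color has been removed.
    """
    out: list[list[str]] = []
    for (color, contig) in sorted(graph._occupancy):
        if color != assembly:
            continue
        seq = graph._occupancy[(color, contig)]
        if not seq:
            continue
        cur = [seq[0]]
        for a, b in zip(seq, seq[1:]):
            if (color, contig) in graph.edges_between(a, b):
                cur.append(b)
            else:
                out.append(cur)
                cur = [b]
        out.append(cur)
    return out
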