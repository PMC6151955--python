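"""Greedy feedback-arc-set removal (Eades-Lin-Smyth Algorithm GR).

Residual directed cycles that survive simplification are broken by the
classic linear-time greedy ordering: repeatedly peel sinks onto a right
list and sources onto a left list; when neither exists, move the vertex
maximizing out-weight minus in-weight to the left list.  Edge
multiplicities act as weights.  All edges pointing leftward in the
resulting sequence are removed, leaving an acyclic graph.  The removed
weight never exceeds half the total, and on sparse graphs the heuristic
is known to be close to optimal.
"""

from __future__ import annotations

from collections import Counter

from .graph import BlockOrder, SupergenomeGraph

__all__ = ["greedy_fas", "remove_edges"]


def greedy_fas(
    graph: SupergenomeGraph,
) -> tuple[BlockOrder, Counter]:
    """Greedy vertex sequence and the multiset of feedback edges.

    Returns the vertex order and a Counter over edge keys
    (tail, head, color, contig) -> multiplicity of all edges pointing
    leftward in that order.  Ties on the degree difference are broken
    by smallest vertex id.
    """
    wout = {v: 0 for v in graph.members}
    win = {v: 0 for v in graph.members}
    out_adj: dict[str, Counter] = {v: Counter() for v in graph.members}
    in_adj: dict[str, Counter] = {v: Counter() for v in graph.members}
    for (t, h, _c, _g), mult in graph.edge_items():
        wout[t] += mult
        win[h] += mult
        out_adj[t][h] += mult
        in_adj[h][t] += mult

    remaining = set(graph.members)
    left: list[str] = []
    right: list[str] = []

    def drop(v: str) -> None:
        remaining.discard(v)
        for w, m in out_adj[v].items():
            if w in remaining:
                win[w] -= m
                in_adj[w].pop(v, None)
        for w, m in in_adj[v].items():
            if w in remaining:
                wout[w] -= m
                out_adj[w].pop(v, None)

    while remaining:
        progress = True
        while progress:
            progress = False
            sinks = sorted(v for v in remaining if wout[v] == 0)
            for v in sinks:
                right.append(v)
                drop(v)
                progress = True
            sources = sorted(v for v in remaining if remaining and win[v] == 0)
            for v in sources:
                if wout[v] == 0:
                    continue  # became isolated; handled as sink next round
                left.append(v)
                drop(v)
                progress = True
        if remaining:
            v = max(remaining, key=lambda u: (wout[u] - win[u], u))
            # deterministic: among maxima prefer smallest id
            best = wout[v] - win[v]
            v = min(u for u in remaining if wout[u] - win[u] == best)
            left.append(v)
            drop(v)

    sequence = left + right[::-1]
    order = BlockOrder(sequence)
    rank = order.ranks
    removed: Counter = Counter()
    for key, mult in graph.edge_items():
        t, h = key[0], key[1]
        if rank[t] > rank[h]:
            removed[key] = mult
    return order, removed


def remove_edges(graph: SupergenomeGraph, removed: Counter) -> SupergenomeGraph:
    """Return a copy of the graph with the given edge keys deleted."""
    g = graph.copy()
    for key in removed:
        g.remove_edge(key)
    return g
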