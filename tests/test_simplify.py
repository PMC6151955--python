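"""Graph simplifiers: contractions, superbubbles, mini-cycle resolution."""

import numpy as np
import pytest

from supercoord.graph import SupergenomeGraph, build_graph
from supercoord.simplify import (
    contract_sources_sinks,
    contract_superbubble,
    dag_simplify,
    find_minicycle_complexes,
    find_superbubbles,
    resolve_complex,
    simplify_to_fixed_point,
)
from supercoord.synthetic import SimulationParams, simulate

from .conftest import chain_msa


def graph_from_edges(vertices, edges):
    g = SupergenomeGraph()
    for v in vertices:
        g.add_vertex(v)
    for i, (t, h) in enumerate(edges):
        g.add_edge(t, h, f"g{i}", "c")
    return g


class TestSourceSinkContraction:
    def test_source_with_single_successor_merged(self):
        g = graph_from_edges("sab", [("s", "a"), ("a", "b"), ("b", "a")])
        out, n = contract_sources_sinks(g)
        assert n == 1
        assert "s" not in out.members
        assert out.members["a"] == ("s", "a")

    def test_isolated_vertex_untouched(self):
        g = graph_from_edges("iab", [("a", "b"), ("b", "a")])
        out, n = contract_sources_sinks(g)
        assert n == 0 and "i" in out.members

    def test_chain_collapses_to_single_vertex(self):
        g = graph_from_edges("abc", [("a", "b"), ("b", "c")])
        out, n = contract_sources_sinks(g)
        assert out.n_vertices == 1
        (members,) = out.members.values()
        assert members == ("a", "b", "c")

    def test_sink_placed_after_its_predecessor(self):
        g = graph_from_edges("abt", [("a", "b"), ("b", "a"), ("a", "t")])
        out, _ = contract_sources_sinks(g)
        assert out.members["a"] == ("a", "t")


class TestSuperbubbles:
    def test_x4_bubble_found(self, x4_graph):
        (bubble,) = find_superbubbles(x4_graph)
        assert bubble.entrance == "B1" and bubble.exit == "B4"
        assert bubble.interior == {"B2", "B3"}

    def test_simple_path_has_no_bubble(self):
        g = graph_from_edges("abc", [("a", "b"), ("b", "c")])
        assert find_superbubbles(g) == []

    def test_interior_cycle_excluded(self):
        g = graph_from_edges(
            "sxyt",
            [("s", "x"), ("s", "y"), ("x", "y"), ("y", "x"), ("x", "t"), ("y", "t")],
        )
        assert find_superbubbles(g) == []

    def test_parallel_edge_bubble_with_empty_interior(self):
        g = SupergenomeGraph()
        for v in "ab":
            g.add_vertex(v)
        g.add_edge("a", "b", "g1", "c")
        g.add_edge("a", "b", "g2", "c")
        (bubble,) = find_superbubbles(g)
        assert bubble.interior == frozenset()
        out = contract_superbubble(g, bubble)
        assert out.members["a"] == ("a", "b")

    def test_x4_contraction_internal_order(self, x4_graph):
        (bubble,) = find_superbubbles(x4_graph)
        out = contract_superbubble(x4_graph, bubble)
        assert out.n_vertices == 1
        assert out.members["B1"] in {
            ("B1", "B2", "B3", "B4"),
            ("B1", "B3", "B2", "B4"),
        }

    def test_nested_bubbles_expand_identically(self):
        # inner bubble a->(b|c)->d nested in s->(a..d|e)->t
        edges = [
            ("s", "a"), ("s", "e"), ("e", "t"),
            ("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"), ("d", "t"),
        ]
        g = graph_from_edges("sabcdet", edges)
        bubbles = find_superbubbles(g)
        assert bubbles[0].entrance == "a"  # innermost first
        g2 = contract_superbubble(g, bubbles[0])
        (outer,) = find_superbubbles(g2)
        g3 = contract_superbubble(g2, outer)
        expanded = g3.members[outer.entrance]
        assert expanded[0] == "s" and expanded[-1] == "t"
        assert set(expanded) == set("sabcdet")
        inner = [v for v in expanded if v in "abcd"]
        assert inner[0] == "a" and inner[-1] == "d"


class TestMiniCycleComplexes:
    def test_reconstructed_five_vertex_complex(self, minicycle_complex_graph):
        (cx,) = find_minicycle_complexes(minicycle_complex_graph)
        assert cx.cycles == frozenset(
            {
                frozenset({"1", "2"}),
                frozenset({"2", "3"}),
                frozenset({"2", "5"}),
            }
        )

    def test_no_bidirectional_pair_no_complex(self, x4_graph):
        assert find_minicycle_complexes(x4_graph) == []

    def test_disjoint_minicycles_give_two_complexes(self):
        g = graph_from_edges(
            "abcd", [("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")]
        )
        assert len(find_minicycle_complexes(g)) == 2

    def test_complexes_partition_and_are_disjoint(self):
        """Complexes cover every mini-cycle; classes share no vertex."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            verts = [f"v{i}" for i in range(n)]
            g = SupergenomeGraph()
            for v in verts:
                g.add_vertex(v)
            color = 0
            for _e in range(int(rng.integers(n, 3 * n))):
                a, b = rng.choice(n, size=2, replace=False)
                g.add_edge(verts[a], verts[b], f"g{color}", "c")
                color += 1
            # plant bidirectional pairs
            for _p in range(int(rng.integers(1, 4))):
                a, b = rng.choice(n, size=2, replace=False)
                g.add_edge(verts[a], verts[b], f"g{color}", "c")
                g.add_edge(verts[b], verts[a], f"g{color + 1}", "c")
                color += 2
            pairs = {
                frozenset((t, h))
                for (t, h, _c, _g) in g.edge_keys()
                if g.has_edge(h, t)
            }
            complexes = find_minicycle_complexes(g)
            covered = set()
            for cx in complexes:
                assert not (covered & cx.cycles)
                covered |= cx.cycles
            assert covered == pairs
            for i, ca in enumerate(complexes):
                for cb in complexes[i + 1 :]:
                    assert not (ca.vertices & cb.vertices)


class TestResolveComplex:
    def test_walkthrough_decisions_and_external_cycle(
        self, minicycle_complex_graph
    ):
        """Best-supported adjacency decided first; the tied adjacency is
        resolved via its already-decided vertex; the external directed
        cycle 3->4->5->3 survives untouched."""
        (cx,) = find_minicycle_complexes(minicycle_complex_graph)
        out = resolve_complex(minicycle_complex_graph, cx)
        directed = {(t, h) for (t, h, _c, _g) in out.edge_keys()}
        assert ("2", "1") not in directed and ("1", "2") in directed
        assert ("3", "2") not in directed and ("2", "3") in directed
        assert ("5", "2") not in directed and ("2", "5") in directed
        # the cycle outside the complex is intact
        assert {("3", "4"), ("4", "5"), ("5", "3")} <= directed

    def test_symmetric_pair_resolved_deterministically(self):
        g = graph_from_edges("ab", [("a", "b"), ("b", "a")])
        (cx,) = find_minicycle_complexes(g)
        out = resolve_complex(g, cx)
        assert {(t, h) for (t, h, _c, _g) in out.edge_keys()} == {("a", "b")}

    def test_majority_direction_wins(self):
        g = SupergenomeGraph()
        for v in "ab":
            g.add_vertex(v)
        for i in range(3):
            g.add_edge("a", "b", f"g{i}", "c")
        g.add_edge("b", "a", "g9", "c")
        (cx,) = find_minicycle_complexes(g)
        out = resolve_complex(g, cx)
        assert out.bundle_mult("a", "b") == 3
        assert out.bundle_mult("b", "a") == 0

    def test_no_minicycle_left_inside_complex(self, minicycle_complex_graph):
        (cx,) = find_minicycle_complexes(minicycle_complex_graph)
        out = resolve_complex(minicycle_complex_graph, cx)
        for pair in cx.cycles:
            v, w = sorted(pair)
            assert not (out.has_edge(v, w) and out.has_edge(w, v))


class TestFixedPoint:
    def test_dag_terminates_immediately_after_inner_pass(self):
        g = build_graph(chain_msa(5, ["g1", "g2"]))
        out = simplify_to_fixed_point(g)
        assert out.n_vertices == 1
        assert out.n_edges == 0

    def test_x4_collapses_to_one_vertex(self, x4_graph):
        out = simplify_to_fixed_point(x4_graph)
        assert out.n_vertices == 1

    def test_complex_resolution_enables_downstream_collapse(
        self, minicycle_complex_graph
    ):
        """The fixed point removes every mini-cycle; once the residual
        external cycle is broken by feedback-arc removal, the graph
        collapses to a single vertex in the order 1..5."""
        from supercoord.mfas import greedy_fas, remove_edges
        from supercoord.simplify import _inner_pass

        out = simplify_to_fixed_point(minicycle_complex_graph)
        assert find_minicycle_complexes(out) == []
        assert out.n_edges < minicycle_complex_graph.n_edges
        _seq, removed = greedy_fas(out)
        out2, _ = _inner_pass(remove_edges(out, removed))
        out2 = dag_simplify(out2)
        assert out2.n_vertices == 1
        (members,) = out2.members.values()
        assert members == ("1", "2", "3", "4", "5")

    def test_expanded_vertex_set_preserved(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            res = simulate(
                SimulationParams(
                    n_blocks=12,
                    n_genomes=3,
                    inversions=2,
                    transpositions=1,
                    seed=int(rng.integers(0, 2**31)),
                )
            )
            g = build_graph(res.msa)
            out = simplify_to_fixed_point(g)
            before = sorted(b for v in g.members.values() for b in v)
            after = sorted(b for v in out.members.values() for b in v)
            assert before == after
            assert out.n_edges <= g.n_edges


class TestDagSimplify:
    def test_dominating_successor_absorbs_source(self):
        # v reaches w, so s goes directly before v; the rest then chains
        g = graph_from_edges("svw", [("s", "v"), ("s", "w"), ("v", "w")])
        out = dag_simplify(g)
        (members,) = out.members.values()
        assert members == ("s", "v", "w")

    def test_incomparable_successors_block_merge(self):
        # diamond: neither v nor w dominates the other, x has two
        # incomparable predecessors -> nothing can be placed
        g = graph_from_edges(
            "svwx", [("s", "v"), ("s", "w"), ("v", "x"), ("w", "x")]
        )
        out = dag_simplify(g)
        assert out.n_vertices == 4

    def test_plain_source_matches_simple_rule(self):
        g = graph_from_edges("sab", [("s", "a"), ("a", "b")])
        assert dag_simplify(g).n_vertices == 1

    def test_cyclic_input_rejected(self):
        g = graph_from_edges("ab", [("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="acyclic"):
            dag_simplify(g)
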