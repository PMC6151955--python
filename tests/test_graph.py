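"""Supergenome graph construction, betweenness cost, exact solver."""

import itertools

import numpy as np
import pytest

from supercoord.graph import (
    BlockOrder,
    betweenness_cost,
    betweenness_triples,
    build_graph,
    color_paths,
    exact_betweenness_order,
)
from supercoord.model import MSA, AlignmentBlock
from supercoord.synthetic import SimulationParams, simulate

from .conftest import chain_msa, iv


class TestBuildGraph:
    def test_x4_edge_list(self, x4_graph):
        assert sorted(x4_graph.edge_keys()) == [
            ("B1", "B2", "g2", "c"),
            ("B1", "B3", "g3", "c"),
            ("B1", "B4", "g1", "c"),
            ("B2", "B4", "g2", "c"),
            ("B3", "B4", "g3", "c"),
        ]

    def test_single_assembly_chain(self):
        g = build_graph(chain_msa(3, ["g1"]))
        assert g.n_edges == 2
        assert g.out_neighbors("a01") == {"a02"}
        assert g.out_neighbors("a02") == {"a03"}

    def test_parallel_edges_from_identical_orders(self):
        g = build_graph(chain_msa(5, ["g1", "g2"]))
        assert g.n_edges == 8  # 4 vertex pairs x 2 colors
        assert g.bundle_mult("a01", "a02") == 2

    def test_equal_starts_rejected(self):
        msa = MSA(
            [
                AlignmentBlock("A", (iv("g1", "c", 0, 10),), 10),
                AlignmentBlock("B", (iv("g1", "c", 0, 12),), 12),
            ]
        )
        with pytest.raises(ValueError, match="start at"):
            build_graph(msa)

    def test_color_path_structure_on_simulated_data(self):
        res = simulate(
            SimulationParams(
                n_blocks=20, n_genomes=4, inversions=2, contig_breaks=2, seed=5
            )
        )
        build_graph(res.msa).validate()


class TestBetweennessTriples:
    def test_x4_yields_the_two_insert_triples(self, x4_graph):
        got = {
            (t.left, t.middle, t.right, t.color)
            for t in betweenness_triples(x4_graph)
        }
        assert got == {("B1", "B2", "B4", "g2"), ("B1", "B3", "B4", "g3")}

    def test_two_edge_path_gives_one_triple(self):
        g = build_graph(chain_msa(3, ["g1"]))
        assert len(betweenness_triples(g)) == 1

    def test_color_mismatch_gives_no_triple(self):
        msa = MSA(
            [
                AlignmentBlock(
                    "hub", (iv("g1", "c", 10, 20), iv("g2", "c", 10, 20)), 10
                ),
                AlignmentBlock("L", (iv("g1", "c", 0, 10),), 10),
                AlignmentBlock("R", (iv("g2", "c", 20, 30),), 10),
            ]
        )
        assert betweenness_triples(build_graph(msa)) == set()


class TestBetweennessCost:
    def test_x4_correct_order_is_free(self, x4_msa):
        assert betweenness_cost(BlockOrder("B1 B2 B3 B4".split()), x4_msa) == 0

    def test_x4_scrambled_order_violates_both_triples(self, x4_msa):
        assert betweenness_cost(BlockOrder("B2 B1 B4 B3".split()), x4_msa) == 2

    def test_unrelated_blocks_cost_nothing(self):
        blocks = [
            AlignmentBlock(f"b{i}", (iv(f"g{i}", "c", 0, 10),), 10)
            for i in range(4)
        ]
        msa = MSA(blocks)
        for perm in itertools.permutations([b.id for b in blocks]):
            assert betweenness_cost(BlockOrder(perm), msa) == 0

    def test_reversal_symmetry(self):
        res = simulate(
            SimulationParams(n_blocks=7, n_genomes=3, inversions=2, seed=9)
        )
        rng = np.random.default_rng(1)
        ids = [b.id for b in res.msa.blocks]
        for _ in range(10):
            order = BlockOrder(rng.permutation(ids))
            assert betweenness_cost(order, res.msa) == betweenness_cost(
                order.reversed(), res.msa
            )

    def test_graph_mode_counts_local_triples_only(self, x4_msa, x4_graph):
        order = BlockOrder("B2 B1 B4 B3".split())
        assert (
            betweenness_cost(order, x4_msa, mode="graph", graph=x4_graph) == 2
        )

    def test_topological_order_of_dag_has_zero_graph_cost(self):
        """Any topological order of an acyclic supergenome graph violates
        no graph-local betweenness triple."""
        rng = np.random.default_rng(4)
        checked = 0
        for trial in range(40):
            res = simulate(
                SimulationParams(
                    n_blocks=int(rng.integers(4, 10)),
                    n_genomes=int(rng.integers(2, 5)),
                    deletions=int(rng.integers(0, 2)),
                    contig_breaks=int(rng.integers(0, 2)),
                    seed=int(rng.integers(0, 2**31)),
                )
            )
            g = build_graph(res.msa)
            if not g.is_acyclic():
                continue
            checked += 1
            topo = BlockOrder(g._kahn_count())
            assert (
                betweenness_cost(topo, res.msa, mode="graph", graph=g) == 0
            )
        assert checked >= 20


def naive_min_cost(msa):
    """Independent brute force: re-derives violations from interval starts."""
    bids = sorted(b.id for b in msa.blocks)
    contig_orders = []
    per_contig: dict = {}
    for b in msa.blocks:
        for interval in b.intervals:
            per_contig.setdefault(
                (interval.assembly, interval.contig), []
            ).append((interval.start, b.id))
    for lst in per_contig.values():
        lst.sort()
        contig_orders.append([bid for _s, bid in lst])
    best = None
    for perm in itertools.permutations(bids):
        rank = {bid: i for i, bid in enumerate(perm)}
        cost = 0
        for ordered in contig_orders:
            for a, m, c in itertools.combinations(ordered, 3):
                ra, rm, rc = rank[a], rank[m], rank[c]
                if not (ra < rm < rc or rc < rm < ra):
                    cost += 1
        best = cost if best is None else min(best, cost)
    return best


class TestExactSolver:
    def test_x4_has_four_optima_in_two_reversal_classes(self, x4_msa):
        order, cost, optima = exact_betweenness_order(
            x4_msa, return_optima=True
        )
        assert cost == 0
        assert len(optima) == 4
        classes = {
            frozenset({o.sequence, o.reversed().sequence}) for o in optima
        }
        assert len(classes) == 2
        assert order.sequence == ("B1", "B2", "B3", "B4")

    def test_two_blocks_both_orders_free(self):
        msa = chain_msa(2, ["g1"])
        _o, cost, optima = exact_betweenness_order(msa, return_optima=True)
        assert cost == 0 and len(optima) == 2

    def test_matches_independent_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            res = simulate(
                SimulationParams(
                    n_blocks=6,
                    n_genomes=3,
                    inversions=1,
                    transpositions=1,
                    seed=int(rng.integers(0, 2**31)),
                )
            )
            _o, cost = exact_betweenness_order(res.msa)
            assert cost == naive_min_cost(res.msa)

    def test_refuses_large_instances(self):
        msa = chain_msa(10, ["g1"])
        with pytest.raises(ValueError, match="capped"):
            exact_betweenness_order(msa, max_blocks=9)


class TestColorPaths:
    def test_x4_paths_per_genome(self, x4_graph):
        assert color_paths(x4_graph, "g2") == [["B1", "B2", "B4"]]
        assert color_paths(x4_graph, "g1") == [["B1", "B4"]]

    def test_single_block_color(self):
        msa = MSA(
            [
                AlignmentBlock(
                    "solo", (iv("g1", "c", 0, 10), iv("g2", "c", 0, 10)), 10
                ),
                AlignmentBlock("next", (iv("g1", "c", 10, 20),), 10),
            ]
        )
        g = build_graph(msa)
        assert color_paths(g, "g2") == [["solo"]]

    def test_absent_color_gives_no_paths(self, x4_graph):
        assert color_paths(x4_graph, "gX") == []
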