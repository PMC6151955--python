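"""Shared fixtures: small hand-constructed alignments and graphs."""

from __future__ import annotations

import pytest

from supercoord.graph import SupergenomeGraph, build_graph
from supercoord.model import MSA, AlignmentBlock, SequenceInterval


def iv(assembly, contig, start, end, strand=1, text=None):
    return SequenceInterval(assembly, contig, start, end, strand, text=text)


def chain_msa(n_blocks: int, genomes: list[str], block_len: int = 20) -> MSA:
    """All genomes share one contig with the blocks in identical order."""
    blocks = []
    for i in range(n_blocks):
        ivs = tuple(
            iv(g, "c", i * block_len, (i + 1) * block_len) for g in genomes
        )
        blocks.append(
            AlignmentBlock(f"a{i + 1:02d}", ivs, block_len)
        )
    lengths = {g: {"c": n_blocks * block_len} for g in genomes}
    return MSA(blocks, lengths)


@pytest.fixture
def x4_msa() -> MSA:
    """Four blocks, three genomes: two independent inserts between the
    flanking blocks.  g1 sees B1,B4; g2 sees B1,B2,B4; g3 sees B1,B3,B4."""
    blocks = [
        AlignmentBlock(
            "B1",
            (iv("g1", "c", 0, 20), iv("g2", "c", 0, 20), iv("g3", "c", 0, 20)),
            20,
        ),
        AlignmentBlock("B2", (iv("g2", "c", 20, 40),), 20),
        AlignmentBlock("B3", (iv("g3", "c", 20, 40),), 20),
        AlignmentBlock(
            "B4",
            (
                iv("g1", "c", 20, 40),
                iv("g2", "c", 40, 60),
                iv("g3", "c", 40, 60),
            ),
            20,
        ),
    ]
    lengths = {"g1": {"c": 40}, "g2": {"c": 60}, "g3": {"c": 60}}
    return MSA(blocks, lengths)


@pytest.fixture
def x4_graph(x4_msa) -> SupergenomeGraph:
    return build_graph(x4_msa)


@pytest.fixture
def minicycle_complex_graph() -> SupergenomeGraph:
    """Synthetic reconstruction of a 5-vertex mini-cycle complex.

    Mini-cycles {1,2}, {2,3}, {2,5} with support decreasing in that
    order and a tie on {2,5}; extra edges (1,3) and (5,3) outside the
    complex and an external directed cycle 3 -> 4 -> 5 -> 3.
    """
    g = SupergenomeGraph()
    for v in "12345":
        g.add_vertex(v)
    edges = [
        ("1", "2", "gA"), ("1", "2", "gB"), ("1", "2", "gC"),
        ("2", "1", "gD"),
        ("2", "3", "gA"), ("2", "3", "gB"),
        ("3", "2", "gD"),
        ("2", "5", "gA"),
        ("5", "2", "gD"),
        ("1", "3", "gE"),
        ("5", "3", "gE"),
        ("3", "4", "gF"), ("4", "5", "gF"),
    ]
    for i, (t, h, c) in enumerate(edges):
        g.add_edge(t, h, c, f"c{i}")
    return g


@pytest.fixture
def filter_maf_path(tmp_path):
    """Twelve-block MAF exercising every curation rule; expected
    removals are blocks 2, 4, 6, 7, 10 and 11 (positional ids)."""
    from supercoord.synthetic import curation_demo_maf

    p = tmp_path / "crafted.maf"
    p.write_text(curation_demo_maf())
    return p
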