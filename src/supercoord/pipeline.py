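"""End-to-end construction of a supergenome coordinate system.

filter -> build graph -> simplify to fixed point -> greedy feedback-arc
removal -> DAG simplification -> seriation -> (optional completion) ->
coordinate assignment.  Fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coordinates import (
    CoordinateMap,
    assign_coordinates,
    insert_completion_blocks,
)
from .filtering import FilterReport, apply_filters
from .graph import BlockOrder, SupergenomeGraph, build_graph
from .maf import complete_msa
from .mfas import greedy_fas, remove_edges
from .model import MSA
from .seriation import distance_table, initial_topological_order, optimize_order
from .simplify import _inner_pass, dag_simplify, simplify_to_fixed_point

__all__ = ["PipelineResult", "build_coordinate_system", "order_blocks"]


@dataclass
class PipelineResult:
    filtered: MSA
    filter_report: FilterReport
    graph: SupergenomeGraph  # initial graph (evaluation reference)
    simplified: SupergenomeGraph
    fas_removed_weight: int
    order: BlockOrder  # expanded block order (retained blocks)
    vertex_order: BlockOrder
    cmap: CoordinateMap | None = None
    stats: dict = field(default_factory=dict)


def order_blocks(
    msa: MSA,
    *,
    path_bound: int = 10,
    max_rounds: int = 100,
) -> tuple[BlockOrder, SupergenomeGraph, SupergenomeGraph, int, BlockOrder]:
    """Order the blocks of an already-filtered MSA.

    Returns (expanded block order, initial graph, simplified DAG,
    removed feedback weight, vertex order).
    """
    g0 = build_graph(msa)
    g = simplify_to_fixed_point(g0)
    vorder_seq, removed = greedy_fas(g)
    removed_weight = sum(removed.values())
    if removed:
        g = remove_edges(g, removed)
    g, _ = _inner_pass(g)
    g = dag_simplify(g)
    vorder = initial_topological_order(g)
    dtable = distance_table(g, l=path_bound)
    vorder = optimize_order(vorder, g, dtable, max_rounds=max_rounds)
    border = BlockOrder(g.expand(vorder))
    return border, g0, g, removed_weight, vorder


def build_coordinate_system(
    msa: MSA,
    *,
    min_block_len: int = 11,
    score_threshold: float = -30.0,
    overlap_tolerance: int = 20,
    path_bound: int = 10,
    max_rounds: int = 100,
    complete: bool = False,
) -> PipelineResult:
    """Run the full pipeline on a raw MSA.

    With ``complete=True`` the retained blocks are complemented by
    unaligned singleton blocks (placed next to their genomic
    predecessor) before coordinates are assigned, so every genome
    position receives a coordinate.
    """
    filtered, report = apply_filters(
        msa,
        min_block_len=min_block_len,
        score_threshold=score_threshold,
        overlap_tolerance=overlap_tolerance,
    )
    border, g0, g, removed_weight, vorder = order_blocks(
        filtered, path_bound=path_bound, max_rounds=max_rounds
    )
    if complete:
        completed = complete_msa(filtered)
        border = insert_completion_blocks(border, completed)
        cmap = assign_coordinates(border, completed)
    else:
        cmap = assign_coordinates(border, filtered)
    return PipelineResult(
        filtered=filtered,
        filter_report=report,
        graph=g0,
        simplified=g,
        fas_removed_weight=removed_weight,
        order=border,
        vertex_order=vorder,
        cmap=cmap,
        stats={
            "input_blocks": len(msa),
            "retained_blocks": len(filtered),
            "initial_vertices": g0.n_vertices,
            "initial_edges": g0.n_edges,
            "final_vertices": g.n_vertices,
            "final_edges": g.n_edges,
            "fas_removed_weight": removed_weight,
        },
    )
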