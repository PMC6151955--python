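"""Quality metrics for a computed supergenome coordinate system.

All metrics compare the final (expanded) block order against the
*initial* supergenome graph, i.e. the adjacencies observed in the input
genomes: block-distance distributions of formerly adjacent blocks,
order/adjacency preservation of successors, edge retention via greedy
betweenness-graph reconstruction, and the contiguity of annotated
features (ORFs/exons) in the new coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .coordinates import CoordinateMap
from .graph import BlockOrder, SupergenomeGraph

__all__ = [
    "distance_distribution",
    "preservation_stats",
    "edge_retention",
    "feature_contiguity",
    "read_features",
]


def _edge_rank_pairs(order: BlockOrder, graph: SupergenomeGraph):
    rank = order.ranks
    for (t, h, color, _contig), mult in graph.edge_items():
        if t in rank and h in rank:
            yield rank[t], rank[h], color, mult


def distance_distribution(
    order: BlockOrder, graph: SupergenomeGraph
) -> dict[tuple[str, str], int]:
    """Histogram of block distances of formerly adjacent blocks.

    For every color edge (A, B): distance = |rank(B) - rank(A)| - 1 in
    the final order (adjacent blocks have distance 0), classified by
    preserved ("+", rank(B) > rank(A)) or inverted ("-") reading
    direction and binned as adjacent / 1-5 / >5.
    """
    hist: Counter = Counter()
    for ra, rb, _color, mult in _edge_rank_pairs(order, graph):
        sign = "+" if rb > ra else "-"
        dist = abs(rb - ra) - 1
        if dist == 0:
            bin_ = "adjacent"
        elif dist <= 5:
            bin_ = "1-5"
        else:
            bin_ = ">5"
        hist[(sign, bin_)] += mult
    for sign in "+-":
        for bin_ in ("adjacent", "1-5", ">5"):
            hist.setdefault((sign, bin_), 0)
    return dict(hist)


def preservation_stats(
    order: BlockOrder, graph: SupergenomeGraph
) -> tuple[float, float, dict[str, tuple[float, float]]]:
    """Fractions of successor relations preserving order and adjacency.

    Over all color edges (A, B): the order is preserved iff
    rank(A) < rank(B); the adjacency additionally requires
    rank(B) = rank(A) + 1.  Returns overall fractions plus a
    per-assembly breakdown; empty graphs score 1.0 vacuously.
    """
    per: dict[str, list[int]] = {}
    for ra, rb, color, mult in _edge_rank_pairs(order, graph):
        cell = per.setdefault(color, [0, 0, 0])
        cell[0] += mult
        if ra < rb:
            cell[1] += mult
            if rb == ra + 1:
                cell[2] += mult
    total = sum(c[0] for c in per.values())
    if total == 0:
        return 1.0, 1.0, {}
    order_frac = sum(c[1] for c in per.values()) / total
    adj_frac = sum(c[2] for c in per.values()) / total
    by_color = {
        color: (c[1] / c[0], c[2] / c[0]) for color, c in per.items() if c[0]
    }
    return order_frac, adj_frac, by_color


def edge_retention(order: BlockOrder, graph: SupergenomeGraph) -> float:
    """Fraction of input edges kept in a greedily rebuilt betweenness graph.

    Starting from no edges: first every edge supported by the total
    order (tail before head) is added; then edges contradicting the
    order are added one by one (deterministic edge-key order) unless
    they would create a betweenness triple violated by the order.
    Returns retained weight / initial weight (1.0 for empty graphs).
    """
    rank = order.ranks
    initial = 0
    retained = 0
    # color -> vertex -> undirected neighbors among retained edges
    nbrs: dict[str, dict[str, set[str]]] = {}

    def note(t: str, h: str, color: str) -> None:
        nbrs.setdefault(color, {}).setdefault(t, set()).add(h)
        nbrs[color].setdefault(h, set()).add(t)

    def creates_violation(t: str, h: str, color: str) -> bool:
        cn = nbrs.get(color, {})
        for (a, b) in ((t, h), (h, t)):
            # new triples with b as the middle vertex
            for k in cn.get(b, ()):
                if k == a:
                    continue
                ra, rb, rk = rank[a], rank[b], rank[k]
                if not (ra < rb < rk or rk < rb < ra):
                    return True
        return False

    contradicting = []
    for (t, h, color, contig), mult in sorted(graph.edge_items()):
        if t not in rank or h not in rank:
            continue
        initial += mult
        if rank[t] < rank[h]:
            retained += mult
            note(t, h, color)
        else:
            contradicting.append((t, h, color, contig, mult))
    for (t, h, color, _contig, mult) in contradicting:
        if not creates_violation(t, h, color):
            retained += mult
            note(t, h, color)
    if initial == 0:
        return 1.0
    return retained / initial


@dataclass
class FeatureReport:
    """Per-feature contiguity in supergenome coordinates."""

    table: pd.DataFrame
    bins: dict[str, int] = field(default_factory=dict)
    broken: int = 0

    @property
    def n_features(self) -> int:
        return len(self.table)


def read_features(path) -> pd.DataFrame:
    """Read genomic features from BED or GFF3 into a plain table.

    Returns columns (contig, start, end, name) with 0-based half-open
    coordinates (pyranges handles the GFF3 1-based conversion).
    """
    import pyranges as pr

    p = str(path)
    if p.endswith((".gff", ".gff3")):
        df = pr.read_gff3(p).df
        name = df["ID"] if "ID" in df.columns else df.index.astype(str)
    elif p.endswith(".bed"):
        df = pr.read_bed(p).df
        name = df["Name"] if "Name" in df.columns else df.index.astype(str)
    else:
        raise ValueError(f"unsupported feature format: {p}")
    return pd.DataFrame(
        {
            "contig": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "name": name.astype(str),
        }
    )


def feature_contiguity(
    cmap: CoordinateMap, features: pd.DataFrame, assembly: str
) -> FeatureReport:
    """Contiguity of annotated features in the supergenome coordinates.

    Per feature: the covering blocks on the reference assembly in
    genomic order, the summed absolute block distances between
    consecutive covering blocks, and a broken flag set when some
    consecutive pair is placed in reverse order.  Distances are binned
    0 / 1-100 / >100.
    """
    rank = cmap.order.ranks
    rows = []
    bins = {"0": 0, "1-100": 0, ">100": 0}
    broken_total = 0
    for rec in features.itertuples(index=False):
        covering = [
            r
            for r in cmap.rows.get((assembly, str(rec.contig)), [])
            if r.start < rec.end and rec.start < r.end
        ]
        blocks = []
        for r in covering:  # genomic order; drop repeats of one block
            if not blocks or blocks[-1] != r.block:
                blocks.append(r.block)
        dist = 0
        broken = False
        for a, b in zip(blocks, blocks[1:]):
            ra, rb = rank[a], rank[b]
            dist += abs(rb - ra) - 1
            if rb < ra:
                broken = True
        if dist == 0:
            bins["0"] += 1
        elif dist <= 100:
            bins["1-100"] += 1
        else:
            bins[">100"] += 1
        broken_total += broken
        rows.append(
            (rec.name, str(rec.contig), rec.start, rec.end, len(blocks), dist, broken)
        )
    table = pd.DataFrame(
        rows,
        columns=["name", "contig", "start", "end", "n_blocks", "distance", "broken"],
    )
    return FeatureReport(table=table, bins=bins, broken=broken_total)
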