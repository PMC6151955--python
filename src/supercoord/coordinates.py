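"""Coordinatization: from a block order to genome-position mappings.

Given a total order of the blocks, global coordinates 1..n (n = total
column count) are assigned column-major in block order.  Every genome
position then maps through its block row's column (gap columns are
skipped; negative-strand rows traverse their columns in reverse, so
genomic order is preserved) to a unique global coordinate per assembly.

Residual border overlaps tolerated by the filter (<= 20 nt) are
resolved here: the later block's overlapping prefix is truncated, so
each genome position maps via the earlier block and the map stays
injective.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import BlockOrder
from .model import MSA, SequenceInterval

__all__ = [
    "CoordinateMap",
    "insert_completion_blocks",
    "assign_coordinates",
    "map_position",
    "export_mapping",
    "read_mapping",
]

_EXPORT_COLUMNS = [
    "assembly",
    "contig",
    "start",
    "end",
    "global_start",
    "global_end",
    "strand",
    "block",
]


@dataclass
class _Row:
    start: int
    end: int
    block: str
    strand: int
    cols: np.ndarray  # column index (0-based) per position, genomic order


@dataclass
class CoordinateMap:
    """The composed coordinate function phi o f of an ordered supergenome."""

    order: BlockOrder
    offsets: dict[str, int]
    n: int
    rows: dict[tuple[str, str], list[_Row]] = field(default_factory=dict)
    _starts: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def finalize(self) -> None:
        for key, lst in self.rows.items():
            lst.sort(key=lambda r: r.start)
            self._starts[key] = [r.start for r in lst]


def _column_indices(iv: SequenceInterval) -> np.ndarray:
    """Block column of each genomic position of a row, in genomic order."""
    if iv.text is None:
        cols = np.arange(iv.length, dtype=np.int64)
    else:
        cols = np.flatnonzero(np.frombuffer(iv.text.encode(), dtype="S1") != b"-")
    if iv.strand == -1:
        cols = cols[::-1]
    return cols


def insert_completion_blocks(order: BlockOrder, completed: MSA) -> BlockOrder:
    """Insert unaligned gap-filler blocks next to their genomic neighbor.

    Blocks of ``completed`` absent from ``order`` (the completion
    singletons) are placed directly after the ordered block whose
    interval immediately precedes them on their contig; a block with no
    genomic predecessor goes directly before its successor, and blocks
    on entirely unaligned contigs are appended at the end sorted by
    (assembly, contig, start).
    """
    in_order = set(order.ranks)
    seq = list(order.sequence)
    after: dict[str, list[tuple[int, str]]] = {}
    before: dict[str, list[tuple[int, str]]] = {}
    tail: list[tuple[str, str, int, str]] = []
    by_contig = completed.intervals_by_contig()
    for (assembly, contig), pairs in sorted(by_contig.items()):
        anchored = [(iv, bid) for iv, bid in pairs if bid in in_order]
        for iv, bid in pairs:
            if bid in in_order:
                continue
            pred = None
            succ = None
            for aiv, abid in anchored:
                if aiv.start < iv.start:
                    pred = abid
                elif succ is None:
                    succ = abid
            if pred is not None:
                after.setdefault(pred, []).append((iv.start, bid))
            elif succ is not None:
                before.setdefault(succ, []).append((iv.start, bid))
            else:
                tail.append((assembly, contig, iv.start, bid))
    out: list[str] = []
    placed: set[str] = set()
    for bid in seq:
        for _, b in sorted(before.get(bid, [])):
            if b not in placed:
                out.append(b)
                placed.add(b)
        out.append(bid)
        for _, b in sorted(after.get(bid, [])):
            if b not in placed:
                out.append(b)
                placed.add(b)
    for _a, _c, _s, b in sorted(tail):
        if b not in placed:
            out.append(b)
            placed.add(b)
    return BlockOrder(out)


def assign_coordinates(order: BlockOrder, msa: MSA) -> CoordinateMap:
    """Build the coordinate map phi o f for an ordered MSA.

    Every block of the MSA must appear in the order.  Global
    coordinates are 1-based internally: the first column of the first
    block is 1 and offset(next) = offset(prev) + l(prev).
    """
    missing = sorted(b.id for b in msa.blocks if b.id not in order)
    if missing:
        raise ValueError(f"blocks missing from the order: {missing}")
    offsets: dict[str, int] = {}
    cursor = 0
    for bid in order:
        if bid in msa:
            offsets[bid] = cursor
            cursor += msa.block(bid).columns
    cmap = CoordinateMap(order=order, offsets=offsets, n=cursor)
    for b in msa.blocks:
        for iv in b.intervals:
            cmap.rows.setdefault((iv.assembly, iv.contig), []).append(
                _Row(iv.start, iv.end, b.id, iv.strand, _column_indices(iv))
            )
    # resolve residual border overlaps: truncate the later row's prefix
    for key, lst in cmap.rows.items():
        lst.sort(key=lambda r: (r.start, r.end))
        kept: list[_Row] = []
        prev_end = 0
        for row in lst:
            if kept and row.start < prev_end:
                trunc = prev_end - row.start
                if trunc >= row.end - row.start:
                    continue  # fully shadowed; cannot occur post-filtering
                row = _Row(
                    row.start + trunc,
                    row.end,
                    row.block,
                    row.strand,
                    row.cols[trunc:],
                )
            kept.append(row)
            prev_end = max(prev_end, row.end)
        cmap.rows[key] = kept
    cmap.finalize()
    return cmap


def map_position(
    cmap: CoordinateMap, assembly: str, contig: str, position: int
) -> int | None:
    """Global coordinate of a genome position, or None if unaligned."""
    key = (assembly, contig)
    if key not in cmap.rows:
        return None
    starts = cmap._starts[key]
    idx = bisect.bisect_right(starts, position) - 1
    if idx < 0:
        return None
    row = cmap.rows[key][idx]
    if position >= row.end:
        return None
    col = int(row.cols[position - row.start])
    return cmap.offsets[row.block] + col + 1


def export_mapping(cmap: CoordinateMap, path) -> None:
    """Write the mapping as a BED-like TSV.

    Columns: assembly, contig, start, end, global_start, global_end,
    strand, block.  Genomic and global coordinates are exported 0-based
    half-open; global_start/global_end span the row's column range.
    Sorted by assembly, contig, start.
    """
    records = []
    for (assembly, contig) in sorted(cmap.rows):
        for row in cmap.rows[(assembly, contig)]:
            off = cmap.offsets[row.block]
            records.append(
                (
                    assembly,
                    contig,
                    row.start,
                    row.end,
                    off + int(row.cols.min()),
                    off + int(row.cols.max()) + 1,
                    "+" if row.strand == 1 else "-",
                    row.block,
                )
            )
    df = pd.DataFrame(records, columns=_EXPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_mapping(path) -> pd.DataFrame:
    """Read back a mapping table written by :func:`export_mapping`."""
    return pd.read_csv(path, sep="\t", dtype={"assembly": str, "contig": str})
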