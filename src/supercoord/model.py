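"""Core data model: sequence intervals, alignment blocks, and whole MSAs.

A genome-wide multiple sequence alignment (gMSA) is a set of alignment
blocks, each aligning sequence intervals drawn from several genome
assemblies.  All coordinates are 0-based, half-open, and always refer to
the forward strand of the contig; the ``strand`` field only records the
reading direction of the row within its block.  A closed interval (i, j)
with i <= j in 1-based inclusive convention corresponds to [i, j+1) here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "SequenceInterval",
    "AlignmentBlock",
    "MSA",
    "project_block",
]


@dataclass(frozen=True)
class SequenceInterval:
    """One aligned genomic segment: the atom of all ordering relations.

    ``start``/``end`` are forward-strand 0-based half-open coordinates
    regardless of ``strand``.  ``text`` optionally carries the gapped
    alignment row (used only for position-to-column mapping); it does not
    participate in equality or hashing.
    """

    assembly: str
    contig: str
    start: int
    end: int
    strand: int = 1
    text: str | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.assembly}.{self.contig}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand!r}")
        if self.text is not None:
            residues = sum(1 for ch in self.text if ch != "-")
            if residues != self.length:
                raise ValueError(
                    f"row text has {residues} residues but interval length "
                    f"is {self.length}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def same_contig(self, other: "SequenceInterval") -> bool:
        return self.assembly == other.assembly and self.contig == other.contig

    def overlap(self, other: "SequenceInterval") -> int:
        """Number of overlapping positions (0 if disjoint or other contig)."""
        if not self.same_contig(other):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "SequenceInterval") -> bool:
        return (
            self.same_contig(other)
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AlignmentBlock:
    """A set of aligned sequence intervals plus the block's column count.

    ``columns`` is the alignment length l(B); every row's ungapped length
    is at most ``columns``.  ``score`` is the (optional) sum-of-pairs
    alignment score from the MAF ``a score=`` field.
    """

    id: str
    intervals: tuple[SequenceInterval, ...]
    columns: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"block {self.id} has no intervals")
        if self.columns < 1:
            raise ValueError(f"block {self.id} has {self.columns} columns")
        for iv in self.intervals:
            if iv.length > self.columns:
                raise ValueError(
                    f"block {self.id}: interval length {iv.length} exceeds "
                    f"column count {self.columns}"
                )

    @property
    def rows(self) -> int:
        return len(self.intervals)

    @property
    def assemblies(self) -> set[str]:
        return {iv.assembly for iv in self.intervals}

    def intervals_of(self, assembly: str) -> tuple[SequenceInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.assembly == assembly)

    @property
    def nucleotides(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def is_injective(self) -> bool:
        """At most one interval per assembly."""
        return len(self.assemblies) == self.rows


def _merge_contig_intervals(
    ivs: list[SequenceInterval],
) -> tuple[SequenceInterval, ...]:
    """Union of intervals on one contig, collapsing overlapping pairs.

    Overlapping comparable pairs (i <= i' <= j <= j') merge into a single
    forward-strand interval; contained (incomparable) pairs are unioned
    the same way, which leaves the result well defined for unfiltered
    input.  Intervals that merely touch (end == start) stay separate.
    """
    ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
    out: list[SequenceInterval] = []
    for iv in ivs:
        if out and iv.start < out[-1].end:
            prev = out[-1]
            out[-1] = SequenceInterval(
                prev.assembly, prev.contig, prev.start, max(prev.end, iv.end), 1
            )
        else:
            out.append(iv)
    return tuple(out)


def project_block(
    block: AlignmentBlock, assembly: str
) -> tuple[SequenceInterval, ...]:
    """Projection pi_G(B): the block's intervals on one assembly.

    Returns an empty tuple when the assembly is absent.  Overlapping
    intervals on the same contig collapse into one interval with strand
    +1; intervals on different contigs are returned unmerged.
    """
    ivs = block.intervals_of(assembly)
    if not ivs:
        return ()
    by_contig: dict[str, list[SequenceInterval]] = {}
    for iv in ivs:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: list[SequenceInterval] = []
    for contig in sorted(by_contig):
        group = by_contig[contig]
        if len(group) == 1:
            out.extend(group)
        else:
            out.extend(_merge_contig_intervals(group))
    return tuple(out)


@dataclass
class MSA:
    """A multiple sequence alignment as a set of blocks with unique ids.

    ``contig_lengths`` maps assembly -> {contig -> length} (the MAF
    ``srcSize`` values, identical in content to UCSC chrom.sizes files).
    """

    blocks: list[AlignmentBlock] = field(default_factory=list)
    contig_lengths: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.blocks]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate block ids: {dupes}")
        self._index = {b.id: b for b in self.blocks}

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def block(self, block_id: str) -> AlignmentBlock:
        return self._index[block_id]

    def __contains__(self, block_id: str) -> bool:
        return block_id in self._index

    @property
    def assemblies(self) -> set[str]:
        out: set[str] = set()
        for b in self.blocks:
            out |= b.assemblies
        return out

    @property
    def nucleotides(self) -> int:
        return sum(b.nucleotides for b in self.blocks)

    def intervals_by_contig(
        self,
    ) -> dict[tuple[str, str], list[tuple[SequenceInterval, str]]]:
        """All (interval, block id) pairs grouped and sorted per contig."""
        out: dict[tuple[str, str], list[tuple[SequenceInterval, str]]] = {}
        for b in self.blocks:
            for iv in b.intervals:
                out.setdefault((iv.assembly, iv.contig), []).append((iv, b.id))
        for pairs in out.values():
            pairs.sort(key=lambda p: (p[0].start, p[0].end, p[1]))
        return out

    def is_injective(self) -> bool:
        return all(b.is_injective() for b in self.blocks)

    def is_irredundant(self) -> bool:
        """No two distinct blocks' projections intersect on any assembly."""
        for pairs in self.intervals_by_contig().values():
            prev_end = -1
            prev_block = None
            for iv, bid in pairs:
                if iv.start < prev_end and bid != prev_block:
                    return False
                if iv.end > prev_end:
                    prev_end = iv.end
                    prev_block = bid
        return True

    def with_blocks(self, blocks: Iterable[AlignmentBlock]) -> "MSA":
        return MSA(list(blocks), {a: dict(c) for a, c in self.contig_lengths.items()})
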