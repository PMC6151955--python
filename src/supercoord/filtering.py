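"""Three-stage curation of input alignments: length, score, overlap.

Stage 1 drops blocks with <= ``min_block_len - 1`` columns (default:
length <= 10 nt).  Stage 2 drops blocks whose length- and row-normalized
sum-of-pairs score falls below a threshold (default -30, the gap
extension penalty of the blastz scoring scheme; equality is kept).
Stage 3, applied only after the first two, removes duplicated or
ambiguous sequence: per assembly and contig, every pair of intervals
from distinct blocks is compared; border overlaps of at most
``overlap_tolerance`` nt (default 20) are ignored, larger overlaps tag
both intervals, and an interval completely contained in another is
tagged regardless of its size.  Every block containing a tagged
interval is removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import MSA, AlignmentBlock

__all__ = ["normalized_score", "apply_filters", "FilterReport"]


def normalized_score(block: AlignmentBlock) -> float:
    """Score per column and per row pair: score / (C(r,2) * l(B)).

    Raises ``ValueError`` for blocks without a score or with fewer than
    two rows, for which the quantity is undefined.
    """
    if block.score is None:
        raise ValueError(f"block {block.id} has no score")
    r = block.rows
    if r < 2:
        raise ValueError(
            f"block {block.id} has {r} row(s); normalized score needs >= 2"
        )
    return block.score / (math.comb(r, 2) * block.columns)


@dataclass
class FilterStage:
    blocks_removed: int = 0
    nucleotides_removed: int = 0


@dataclass
class FilterReport:
    """Per-stage removal counts and overall fractions."""

    input_blocks: int = 0
    input_nucleotides: int = 0
    length: FilterStage = field(default_factory=FilterStage)
    score: FilterStage = field(default_factory=FilterStage)
    overlap: FilterStage = field(default_factory=FilterStage)
    score_exempt: int = 0  # blocks without a score or with a single row

    @property
    def blocks_removed(self) -> int:
        return (
            self.length.blocks_removed
            + self.score.blocks_removed
            + self.overlap.blocks_removed
        )

    @property
    def nucleotides_removed(self) -> int:
        return (
            self.length.nucleotides_removed
            + self.score.nucleotides_removed
            + self.overlap.nucleotides_removed
        )

    @property
    def removed_block_fraction(self) -> float:
        if self.input_blocks == 0:
            return 0.0
        return self.blocks_removed / self.input_blocks

    @property
    def removed_nucleotide_fraction(self) -> float:
        if self.input_nucleotides == 0:
            return 0.0
        return self.nucleotides_removed / self.input_nucleotides

    def to_dict(self) -> dict:
        return {
            "input_blocks": self.input_blocks,
            "input_nucleotides": self.input_nucleotides,
            "stages": {
                name: {
                    "blocks_removed": st.blocks_removed,
                    "nucleotides_removed": st.nucleotides_removed,
                }
                for name, st in (
                    ("length", self.length),
                    ("score", self.score),
                    ("overlap", self.overlap),
                )
            },
            "score_exempt": self.score_exempt,
            "removed_block_fraction": self.removed_block_fraction,
            "removed_nucleotide_fraction": self.removed_nucleotide_fraction,
        }


def _overlap_tagged_blocks(msa: MSA, tolerance: int) -> set[str]:
    """Ids of blocks holding an interval tagged by the overlap filter.

    The tolerance applies per overlapping pair.  Comparisons are made on
    forward-strand intervals per assembly+contig across distinct blocks
    only.
    """
    tagged: set[str] = set()
    for pairs in msa.intervals_by_contig().values():
        # sweep over start-sorted intervals; active set holds intervals
        # whose end may still exceed the next start
        active: list[tuple] = []  # (end, start, block_id)
        for iv, bid in pairs:
            active = [a for a in active if a[0] > iv.start]
            for (aend, astart, abid) in active:
                if abid == bid:
                    continue
                contained = (astart <= iv.start and iv.end <= aend) or (
                    iv.start <= astart and aend <= iv.end
                )
                ov = min(aend, iv.end) - max(astart, iv.start)
                if contained or ov > tolerance:
                    tagged.add(bid)
                    tagged.add(abid)
            active.append((iv.end, iv.start, bid))
    return tagged


def apply_filters(
    msa: MSA,
    min_block_len: int = 11,
    score_threshold: float = -30.0,
    overlap_tolerance: int = 20,
) -> tuple[MSA, FilterReport]:
    """Run the three curation stages in order and report what was removed.

    Blocks without a score (or with a single row) are exempt from the
    score stage and counted in ``report.score_exempt``.  The pipeline is
    idempotent: filtering an already-filtered MSA removes nothing.
    """
    report = FilterReport(
        input_blocks=len(msa), input_nucleotides=msa.nucleotides
    )

    kept: list[AlignmentBlock] = []
    for b in msa.blocks:
        if b.columns < min_block_len:
            report.length.blocks_removed += 1
            report.length.nucleotides_removed += b.nucleotides
        else:
            kept.append(b)

    kept2: list[AlignmentBlock] = []
    for b in kept:
        if b.score is None or b.rows < 2:
            report.score_exempt += 1
            kept2.append(b)
        elif normalized_score(b) < score_threshold:
            report.score.blocks_removed += 1
            report.score.nucleotides_removed += b.nucleotides
        else:
            kept2.append(b)

    stage2 = msa.with_blocks(kept2)
    tagged = _overlap_tagged_blocks(stage2, overlap_tolerance)
    kept3: list[AlignmentBlock] = []
    for b in kept2:
        if b.id in tagged:
            report.overlap.blocks_removed += 1
            report.overlap.nucleotides_removed += b.nucleotides
        else:
            kept3.append(b)

    return msa.with_blocks(kept3), report
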