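"""Synthetic multi-genome alignments with known ground-truth order.

The generator emulates the block structure of a genome-wide MSA: an
ancestral sequence of alignment blocks is mutated independently per
genome by inversions (segment reversed, strands flipped),
transpositions (segment relocated), deletions, and duplications
(copies become new singleton blocks so blocks stay injective), then
optionally fragmented into contigs.  Coordinates are consistent by
construction and the MAF row texts are uninformative ("A" runs): the
ordering pipeline only ever reads coordinates, never residues.

Every breakpoint introduced by a rearrangement creates an ambiguous
adjacency in the supergenome graph, which is exactly the difficulty the
ordering heuristics must resolve; the operation log plus the ancestral
order provide exact expected values for the evaluation metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import BlockOrder
from .model import MSA, AlignmentBlock, SequenceInterval

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "simulate",
    "curation_demo_maf",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated alignment.

    Counts are per genome; ``contig_breaks`` cuts each genome into that
    many + 1 contigs.  ``score_scale`` sets each block's score to
    l(B) * C(r, 2) * score_scale, so the normalized score equals
    ``score_scale`` and the score filter can be exercised at any
    threshold.  The seed fixes the output bit-exactly.
    """

    n_blocks: int = 50
    n_genomes: int = 5
    block_len_range: tuple[int, int] = (20, 200)
    inversions: "int | dict[str, int]" = 0
    transpositions: "int | dict[str, int]" = 0
    deletions: "int | dict[str, int]" = 0
    duplications: "int | dict[str, int]" = 0
    contig_breaks: int = 0
    score_scale: float = 1.0
    seed: int = 0

    def count_for(self, name: str, genome: str) -> int:
        """Per-genome operation count: ints apply to every genome."""
        value = getattr(self, name)
        if isinstance(value, dict):
            return int(value.get(genome, 0))
        return int(value)

    def _max_count(self, name: str) -> int:
        value = getattr(self, name)
        if isinstance(value, dict):
            return max(value.values(), default=0)
        return value

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_genomes < 1:
            raise ValueError("need at least one block and one genome")
        lo, hi = self.block_len_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad block length range {self.block_len_range}")
        for name in (
            "inversions",
            "transpositions",
            "deletions",
            "duplications",
        ):
            if self._max_count(name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.contig_breaks < 0:
            raise ValueError("contig_breaks must be >= 0")
        total_del = self._max_count("deletions") * max(1, self.n_blocks // 10)
        if self._max_count("deletions") and total_del >= self.n_blocks:
            raise ValueError(
                "requested deletions could remove every block of a genome"
            )


@dataclass
class SimulationResult:
    msa: MSA
    truth: BlockOrder
    operations: list[dict] = field(default_factory=list)
    params: SimulationParams | None = None


def _segment(rng, n: int, max_len: int) -> tuple[int, int]:
    length = int(rng.integers(1, max_len + 1))
    length = min(length, n)
    start = int(rng.integers(0, n - length + 1))
    return start, start + length


def simulate(params: SimulationParams) -> SimulationResult:
    """Generate an MSA from a mutated ancestral block order.

    Returns the in-memory MSA (write it with :func:`supercoord.maf.write_maf`),
    the ancestral order over the original block ids, and the per-genome
    operation log.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_blocks
    width = max(4, len(str(n)))
    ids = [f"b{i:0{width}d}" for i in range(1, n + 1)]
    lo, hi = params.block_len_range
    lengths = {
        bid: int(rng.integers(lo, hi + 1)) for bid in ids
    }
    seg_max = max(1, n // 10)
    genomes = [f"g{j}" for j in range(1, params.n_genomes + 1)]
    ops: list[dict] = []
    layouts: dict[str, list[tuple[str, int]]] = {}
    extra_blocks: list[tuple[str, str, int]] = []  # (new id, genome, length)
    dup_counter = 0
    for g in genomes:
        seq: list[tuple[str, int]] = [(bid, 1) for bid in ids]
        for _ in range(params.count_for("inversions", g)):
            a, b = _segment(rng, len(seq), seg_max)
            seq[a:b] = [(bid, -s) for bid, s in reversed(seq[a:b])]
            ops.append({"genome": g, "op": "inversion", "span": (a, b)})
        for _ in range(params.count_for("transpositions", g)):
            a, b = _segment(rng, len(seq), seg_max)
            seg = seq[a:b]
            rest = seq[:a] + seq[b:]
            pos = int(rng.integers(0, len(rest) + 1))
            seq = rest[:pos] + seg + rest[pos:]
            ops.append(
                {"genome": g, "op": "transposition", "span": (a, b), "to": pos}
            )
        for _ in range(params.count_for("deletions", g)):
            if len(seq) <= 1:
                break
            a, b = _segment(rng, len(seq), min(seg_max, len(seq) - 1))
            ops.append(
                {
                    "genome": g,
                    "op": "deletion",
                    "blocks": [bid for bid, _ in seq[a:b]],
                }
            )
            seq = seq[:a] + seq[b:]
        for _ in range(params.count_for("duplications", g)):
            a, b = _segment(rng, len(seq), seg_max)
            copies = []
            for bid, s in seq[a:b]:
                dup_counter += 1
                nid = f"d{dup_counter:0{width}d}"
                base = bid if not bid.startswith("d") else bid
                extra_blocks.append((nid, g, lengths.get(base, lo)))
                lengths[nid] = lengths.get(base, lo)
                copies.append((nid, s))
            pos = int(rng.integers(0, len(seq) + 1))
            seq = seq[:pos] + copies + seq[pos:]
            ops.append(
                {
                    "genome": g,
                    "op": "duplication",
                    "blocks": [bid for bid, _ in copies],
                    "to": pos,
                }
            )
        layouts[g] = seq

    # fragment into contigs and assign forward-strand coordinates
    intervals: dict[str, list[SequenceInterval]] = {bid: [] for bid in ids}
    for nid, _g, _len in extra_blocks:
        intervals[nid] = []
    contig_lengths: dict[str, dict[str, int]] = {}
    for g in genomes:
        seq = layouts[g]
        cuts = set()
        if params.contig_breaks and len(seq) > 1:
            k = min(params.contig_breaks, len(seq) - 1)
            cuts = set(
                int(c)
                for c in rng.choice(
                    np.arange(1, len(seq)), size=k, replace=False
                )
            )
        contig_no = 1
        pos = 0
        contig = f"c{contig_no}"
        contig_lengths.setdefault(g, {})
        for idx, (bid, strand) in enumerate(seq):
            if idx in cuts:
                contig_lengths[g][contig] = pos
                contig_no += 1
                contig = f"c{contig_no}"
                pos = 0
            length = lengths[bid]
            intervals[bid].append(
                SequenceInterval(g, contig, pos, pos + length, strand)
            )
            pos += length
        contig_lengths[g][contig] = pos

    blocks: list[AlignmentBlock] = []
    for bid in ids + [nid for nid, _g, _l in extra_blocks]:
        ivs = tuple(intervals[bid])
        if not ivs:
            continue  # deleted from every genome
        r = len(ivs)
        score = lengths[bid] * math.comb(r, 2) * params.score_scale
        blocks.append(
            AlignmentBlock(
                id=bid,
                intervals=ivs,
                columns=lengths[bid],
                score=score if r >= 2 else None,
            )
        )
    msa = MSA(blocks, contig_lengths)
    truth = BlockOrder(bid for bid in ids if intervals[bid])
    return SimulationResult(
        msa=msa, truth=truth, operations=ops, params=params
    )


def curation_demo_maf() -> str:
    """A twelve-block MAF exercising every curation rule of the filter.

    Two genomes on one contig each.  Blocks 2 (length 10), 4 (normalized
    score -31), 6+7 (border overlap 30 nt), and 10+11 (complete
    containment) violate a rule; blocks 1, 3, 5 (score exactly at the
    -30 threshold), 8+9 (border overlap 15 nt, tolerated) and 12
    survive the default settings.
    """
    spec = [
        # (g1 start, length, normalized score)
        (0, 50, 20),
        (60, 10, 20),      # removed: length <= 10
        (80, 11, 20),
        (100, 50, -31),    # removed: score < -30
        (160, 50, -30),    # kept: boundary
        (220, 80, 20),     # removed: overlaps block 7 by 30
        (270, 80, 20),     # removed: overlaps block 6 by 30
        (360, 80, 20),     # kept: overlaps block 9 by only 15
        (425, 75, 20),
        (520, 20, 20),     # removed: contained in block 11
        (510, 90, 20),     # removed: contains block 10
        (700, 60, 20),
    ]
    lines = ["##maf version=1", ""]
    for i, (start, length, norm) in enumerate(spec):
        score = norm * length  # two rows: a single pair
        text = "A" * length
        lines.append(f"a score={score}")
        lines.append(f"s g1.c1 {start} {length} + 1000 {text}")
        lines.append(f"s g2.c1 {i * 100} {length} + 1200 {text}")
        lines.append("")
    return "\n".join(lines)
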