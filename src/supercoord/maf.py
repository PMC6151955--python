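"""MAF alignment input/output and MSA completion.

Reading and writing go through Biopython's ``Bio.AlignIO`` MAF support.
Row source names are split into assembly and contig at the first
occurrence of a configurable splitter (UCSC ``assembly.contig``
convention).  All coordinates are normalized to the forward strand on
input: a "-" strand row with MAF start s and size n on a contig of
srcSize L becomes the forward interval [L - s - n, L - s).
"""

from __future__ import annotations

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import MSA, AlignmentBlock, SequenceInterval

__all__ = [
    "read_maf",
    "write_maf",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "complete_msa",
]


class MafParseError(ValueError):
    pass


def _split_src(src: str, splitter: str) -> tuple[str, str]:
    if splitter in src:
        assembly, contig = src.split(splitter, 1)
    else:
        # single-token sources: assembly doubles as its only contig
        assembly, contig = src, src
    return assembly, contig


def read_maf(path, splitter: str = ".", id_prefix: str = "b") -> MSA:
    """Read a MAF file into an :class:`MSA`.

    One :class:`AlignmentBlock` is created per ``a`` record; every ``s``
    row becomes a forward-strand-normalized :class:`SequenceInterval`.
    Block ids are ``<id_prefix><ordinal>`` zero-padded in file order.
    ``i``/``q``/``e`` lines are ignored by the underlying parser.

    Raises :class:`MafParseError` on malformed records or coordinates
    that exceed the declared source size.
    """
    blocks: list[AlignmentBlock] = []
    contig_lengths: dict[str, dict[str, int]] = {}
    with open(path) as handle:
        try:
            alignments = list(AlignIO.parse(handle, "maf"))
        except ValueError as exc:  # pragma: no cover - message passthrough
            raise MafParseError(f"{path}: malformed MAF: {exc}") from exc
    width = max(4, len(str(len(alignments))))
    for ordinal, aln in enumerate(alignments, start=1):
        intervals: list[SequenceInterval] = []
        for rec in aln:
            ann = rec.annotations
            start, size = int(ann["start"]), int(ann["size"])
            strand = 1 if ann["strand"] in (1, "+", "+1") else -1
            src_size = int(ann["srcSize"])
            if size <= 0:
                raise MafParseError(
                    f"{path}: block {ordinal}, row {rec.id!r}: "
                    f"non-positive size {size}"
                )
            if start < 0 or start + size > src_size:
                raise MafParseError(
                    f"{path}: block {ordinal}, row {rec.id!r}: "
                    f"start {start} + size {size} exceeds srcSize {src_size}"
                )
            assembly, contig = _split_src(rec.id, splitter)
            if strand == 1:
                fstart = start
            else:
                fstart = src_size - start - size
            intervals.append(
                SequenceInterval(
                    assembly,
                    contig,
                    fstart,
                    fstart + size,
                    strand,
                    text=str(rec.seq),
                )
            )
            contig_lengths.setdefault(assembly, {})[contig] = src_size
        score = None
        raw = getattr(aln, "_annotations", {}) or {}
        if "score" in raw:
            score = float(raw["score"])
        blocks.append(
            AlignmentBlock(
                id=f"{id_prefix}{ordinal:0{width}d}",
                intervals=tuple(intervals),
                columns=aln.get_alignment_length(),
                score=score,
            )
        )
    return MSA(blocks, contig_lengths)


def _row_text(iv: SequenceInterval, columns: int) -> str:
    if iv.text is not None:
        return iv.text
    # no stored row: emit an ungapped placeholder padded to block width
    return "A" * iv.length + "-" * (columns - iv.length)


def write_maf(msa: MSA, path, splitter: str = ".") -> None:
    """Write an :class:`MSA` as MAF, blocks in current order.

    Scores are preserved verbatim when present.  Negative-strand rows are
    converted back to MAF reverse-strand coordinates, which requires the
    contig length to be known from ``msa.contig_lengths``.
    """
    alignments = []
    for block in msa.blocks:
        records = []
        for iv in block.intervals:
            src_size = msa.contig_lengths.get(iv.assembly, {}).get(iv.contig)
            if src_size is None:
                if iv.strand == -1:
                    raise ValueError(
                        f"block {block.id}: cannot write '-' strand row for "
                        f"{iv.assembly}.{iv.contig} without its contig length"
                    )
                src_size = iv.end
            start = iv.start if iv.strand == 1 else src_size - iv.end
            src = iv.assembly if iv.assembly == iv.contig else (
                f"{iv.assembly}{splitter}{iv.contig}"
            )
            records.append(
                SeqRecord(
                    Seq(_row_text(iv, block.columns)),
                    id=src,
                    annotations={
                        "start": start,
                        "size": iv.length,
                        "strand": iv.strand,
                        "srcSize": src_size,
                    },
                )
            )
        aln = MultipleSeqAlignment(records)
        if block.score is not None:
            aln._annotations = {"score": repr(block.score)}
        alignments.append(aln)
    with open(path, "w") as handle:
        AlignIO.write(alignments, handle, "maf")


def read_chrom_sizes(path, splitter: str = ".") -> dict[str, dict[str, int]]:
    """Read a two-column TSV of ``assembly.contig<TAB>length`` rows."""
    out: dict[str, dict[str, int]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            assembly, contig = _split_src(parts[0], splitter)
            out.setdefault(assembly, {})[contig] = int(parts[1])
    return out


def write_chrom_sizes(
    contig_lengths: dict[str, dict[str, int]], path, splitter: str = "."
) -> None:
    with open(path, "w") as handle:
        for assembly in sorted(contig_lengths):
            for contig in sorted(contig_lengths[assembly]):
                name = assembly if assembly == contig else (
                    f"{assembly}{splitter}{contig}"
                )
                handle.write(f"{name}\t{contig_lengths[assembly][contig]}\n")


def complete_msa(
    msa: MSA,
    contig_lengths: dict[str, dict[str, int]] | None = None,
    id_prefix: str = "u",
) -> MSA:
    """Complete the MSA by adding every unaligned interval as a singleton.

    After completion the union of projections covers every position of
    every contig listed in ``contig_lengths`` (default: the lengths
    stored on the MSA).  Original blocks are untouched; the added blocks
    have one forward-strand interval, no score, and ids ``u0001``, ...

    The MSA must be irredundant, otherwise coverage gaps are ill defined.
    """
    if contig_lengths is None:
        contig_lengths = msa.contig_lengths
    if not msa.is_irredundant():
        raise ValueError(
            "MSA is not irredundant; apply the overlap filter before "
            "completing it"
        )
    by_contig = msa.intervals_by_contig()
    for (assembly, contig) in by_contig:
        if contig_lengths.get(assembly, {}).get(contig) is None:
            raise ValueError(
                f"no contig length known for {assembly}.{contig}"
            )
    gaps: list[SequenceInterval] = []
    for assembly in sorted(contig_lengths):
        for contig in sorted(contig_lengths[assembly]):
            length = contig_lengths[assembly][contig]
            covered = by_contig.get((assembly, contig), [])
            cursor = 0
            for iv, _bid in covered:
                if iv.start > cursor:
                    gaps.append(
                        SequenceInterval(assembly, contig, cursor, iv.start)
                    )
                cursor = max(cursor, iv.end)
            if cursor < length:
                gaps.append(SequenceInterval(assembly, contig, cursor, length))
    width = max(4, len(str(len(gaps))))
    new_blocks = list(msa.blocks)
    for ordinal, iv in enumerate(gaps, 1):
        new_blocks.append(
            AlignmentBlock(
                id=f"{id_prefix}{ordinal:0{width}d}",
                intervals=(iv,),
                columns=iv.length,
            )
        )
    out = msa.with_blocks(new_blocks)
    out.contig_lengths = {a: dict(c) for a, c in contig_lengths.items()}
    return out
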