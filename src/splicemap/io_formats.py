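"""Readers and writers for FASTA, FASTQ, SAM, annotation and truth tables.

All dialects are plain text.  Coordinates in every table are 0-based
half-open; the single 0-based -> 1-based conversion of the whole package
happens in :func:`write_sam`.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Iterator, Optional, TextIO, Union

from .model import (
    GapType,
    IndelEvent,
    Read,
    ReferenceSequence,
    SamRecord,
    SplitAlignment,
    TruthRecord,
)

Source = Union[str, os.PathLike, TextIO]


def _open_text(source: Source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def parse_fasta(source: Source) -> list[ReferenceSequence]:
    """Parse a (multi-record) FASTA stream into reference sequences.

    Lowercase bases are uppercased; record order is preserved.  Empty input
    or duplicate record names raise ``ValueError``.
    """
    fh, close = _open_text(source)
    try:
        records: list[ReferenceSequence] = []
        seen: set[str] = set()
        name: Optional[str] = None
        chunks: list[str] = []

        def flush():
            if name is None:
                return
            if name in seen:
                raise ValueError(f"duplicate FASTA record name: {name!r}")
            seen.add(name)
            records.append(ReferenceSequence(name, "".join(chunks).upper()))

        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA data before first header")
                chunks.append(line)
        flush()
        if not records:
            raise ValueError("empty FASTA input")
        return records
    finally:
        if close:
            fh.close()


def write_fasta(records: Iterable[ReferenceSequence], out: Source, width: int = 70) -> None:
    fh, close = _open_text(out, "w")
    try:
        for rec in records:
            fh.write(f">{rec.name}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    finally:
        if close:
            fh.close()


def parse_fastq(source: Source) -> Iterator[Read]:
    """Lazily yield reads from a 4-line-record FASTQ stream."""
    fh, close = _open_text(source)
    try:
        while True:
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header: {header!r}")
            rid = header[1:].split()[0]
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus or not qual:
                raise ValueError(f"truncated FASTQ record for read {rid!r}")
            if len(qual) != len(seq):
                raise ValueError(
                    f"read {rid!r}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield Read(rid, seq.upper(), qual)
    finally:
        if close:
            fh.close()


def write_fastq(reads: Iterable[Read], out: Source) -> None:
    fh, close = _open_text(out, "w")
    try:
        for r in reads:
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# CIGAR construction
# ---------------------------------------------------------------------------

_GAP_OP = {GapType.INTRON: "N", GapType.DELETION: "D", GapType.INSERTION: "I"}


def cigar_from_split(
    alignment: SplitAlignment, read_length: int, gap_types: list[GapType]
) -> str:
    """Build a CIGAR string from an alignment's blocks and classified gaps.

    Introns emit N, deletions D, insertions I; unaligned read prefix/suffix
    emit S.  M/I/S lengths sum to the read length by construction.
    """
    blocks = alignment.blocks
    gaps = alignment.gaps()
    if len(gap_types) != len(gaps):
        raise ValueError("one gap type required per split position")
    ops: list[tuple[int, str]] = []
    if blocks[0][2] > 0:
        ops.append((blocks[0][2], "S"))
    for i, b in enumerate(blocks):
        ops.append((b[1] - b[0], "M"))
        if i < len(gaps):
            donor_end, acceptor_start, read_gap = gaps[i]
            gt = gap_types[i]
            if gt is GapType.INSERTION:
                if read_gap <= 0:
                    raise ValueError("insertion gap without skipped read bases")
                ops.append((read_gap, "I"))
            else:
                if read_gap != 0:
                    raise ValueError("unexplained interior read bases at a reference gap")
                ops.append((acceptor_start - donor_end, _GAP_OP[gt]))
    tail = read_length - blocks[-1][3]
    if tail < 0:
        raise ValueError("blocks extend past the read end")
    if tail > 0:
        ops.append((tail, "S"))
    consumed = sum(n for n, op in ops if op in "MIS")
    if consumed != read_length:
        raise ValueError(
            f"CIGAR consumes {consumed} read bases, read length is {read_length}"
        )
    return "".join(f"{n}{op}" for n, op in ops)


def cigar_read_ref_spans(cigar: str) -> tuple[int, int]:
    """(read bases consumed, reference bases consumed) of a CIGAR string."""
    read = ref = 0
    for n, op in iter_cigar(cigar):
        if op in "MIS=X":
            read += n
        if op in "MDN=X":
            ref += n
    return read, ref


def iter_cigar(cigar: str) -> Iterator[tuple[int, str]]:
    if cigar == "*":
        return
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR: {cigar!r}")
            yield int(num), ch
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR: {cigar!r}")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(
    records: Iterable[SamRecord],
    references: Iterable[ReferenceSequence],
    out: Source,
) -> None:
    """Write a SAM v1.6 file: @HD and @SQ header lines, then the records.

    Record ``pos`` is 0-based internally and printed 1-based here.
    """
    refs = list(references)
    known = {r.name for r in refs}
    fh, close = _open_text(out, "w")
    try:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for r in refs:
            fh.write(f"@SQ\tSN:{r.name}\tLN:{len(r.sequence)}\n")
        for rec in records:
            if not rec.is_unmapped and rec.rname not in known:
                raise ValueError(f"record {rec.qname!r} on unknown reference {rec.rname!r}")
            fields = [
                rec.qname,
                str(rec.flag),
                rec.rname if not rec.is_unmapped else "*",
                str(rec.pos + 1 if not rec.is_unmapped else 0),
                str(rec.mapq),
                rec.cigar,
                "*",
                "0",
                "0",
                rec.seq,
                rec.qual,
                *rec.tags,
            ]
            fh.write("\t".join(fields) + "\n")
    finally:
        if close:
            fh.close()


def parse_sam(source: Source) -> Iterator[SamRecord]:
    """Parse SAM alignment lines (headers skipped); pos converted to 0-based."""
    fh, close = _open_text(source)
    try:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ValueError(f"malformed SAM line: {line!r}")
            yield SamRecord(
                qname=f[0],
                flag=int(f[1]),
                rname=f[2],
                pos=int(f[3]) - 1,
                mapq=int(f[4]),
                cigar=f[5],
                seq=f[9],
                qual=f[10],
                tags=tuple(f[11:]),
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Annotation table (TSV: chrom, strand, intron_start, intron_end)
# ---------------------------------------------------------------------------

def read_annotation(source: Source) -> set[tuple[str, int, int]]:
    """Read annotated introns; returns {(chrom, intron_start, intron_end)}."""
    fh, close = _open_text(source)
    try:
        introns = set()
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, _strand, start, end = line.split("\t")[:4]
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"empty intron interval in annotation: {line!r}")
            introns.add((chrom, start, end))
        return introns
    finally:
        if close:
            fh.close()


def write_annotation(
    introns: Iterable[tuple[str, str, int, int]], out: Source
) -> None:
    fh, close = _open_text(out, "w")
    try:
        for chrom, strand, start, end in introns:
            fh.write(f"{chrom}\t{strand}\t{start}\t{end}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------
# Columns: read_id, chrom, strand, blocks ("start-end,start-end,..."),
# mismatch positions ("p1,p2" or "."), indels ("K:refpos:len:readpos;..." or ".").

def _format_blocks(blocks) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _parse_blocks(text: str) -> tuple[tuple[int, int], ...]:
    blocks = []
    for part in text.split(","):
        try:
            s, e = part.split("-")
            blocks.append((int(s), int(e)))
        except ValueError as exc:
            raise ValueError(f"malformed block string: {text!r}") from exc
    return tuple(blocks)


def write_truth(records: Iterable[TruthRecord], out: Source) -> None:
    fh, close = _open_text(out, "w")
    try:
        for rec in records:
            mism = ",".join(str(p) for p in rec.mismatch_positions) or "."
            indels = (
                ";".join(
                    f"{iv.kind}:{iv.ref_pos}:{iv.length}:{iv.read_pos}" for iv in rec.indels
                )
                or "."
            )
            fh.write(
                "\t".join(
                    [rec.read_id, rec.rname, rec.strand, _format_blocks(rec.blocks), mism, indels]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


def read_truth(source: Source) -> list[TruthRecord]:
    fh, close = _open_text(source)
    try:
        records = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, chrom, strand, blocks, mism, indels = line.split("\t")
            mism_pos = tuple(int(p) for p in mism.split(",")) if mism != "." else ()
            events = []
            if indels != ".":
                for part in indels.split(";"):
                    kind, ref_pos, length, read_pos = part.split(":")
                    events.append(
                        IndelEvent(kind, int(ref_pos), int(length), int(read_pos))
                    )
            records.append(
                TruthRecord(rid, chrom, strand, _parse_blocks(blocks), mism_pos, tuple(events))
            )
        return records
    finally:
        if close:
            fh.close()
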