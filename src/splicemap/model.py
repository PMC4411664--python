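"""Core domain types shared across the mapping pipeline.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open.  Conversion to the 1-based
SAM convention happens in exactly one place (``io_formats.write_sam``).

Read coordinates of an alignment always refer to the *strand-oriented* read:
for a reverse-strand placement the read is reverse complemented first and all
block/mismatch coordinates refer to that oriented sequence.  This mirrors how
SAM stores SEQ for reverse-strand records, so no coordinate flipping is ever
needed at output time.  :meth:`RawAlignment.mismatches_original` maps mismatch
positions back to coordinates of the read as it appeared in the FASTQ.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentCategory(enum.Enum):
    """Four-way classification of an initial (ungapped) alignment."""

    FULL = "full"
    CANDIDATE_SINGLE_SPLIT = "candidate_single_split"
    PARTIAL = "partial"
    CANDIDATE_MULTI_SPLIT = "candidate_multi_split"


class GapType(enum.Enum):
    """Type of the reference/read gap at one split position."""

    INSERTION = "insertion"
    DELETION = "deletion"
    INTRON = "intron"


@dataclass(frozen=True)
class ReferenceSequence:
    """One reference sequence (chromosome / genome segment)."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("reference name must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"reference {self.name!r} is empty")
        if not self.sequence.isupper():
            object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    """A single-end sequencing read."""

    id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self):
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RawAlignment:
    """An ungapped placement of (part of) a read on one reference.

    ``read_start``/``read_end`` delimit the aligned interval of the oriented
    read; ``ref_start`` is the reference position of ``read_start``.  Raw
    alignments are gapless, so the reference span equals the read span.
    """

    read_id: str
    rname: str
    strand: str  # '+' or '-'
    ref_start: int
    read_start: int
    read_end: int
    read_length: int
    mismatches: tuple[int, ...]  # oriented read coords, inside [read_start, read_end)
    end_to_end: bool
    seed_anchor: str  # 'start' or 'end' (of the oriented read)

    @property
    def ref_end(self) -> int:
        return self.ref_start + (self.read_end - self.read_start)

    @property
    def n_clipped(self) -> int:
        return self.read_start + (self.read_length - self.read_end)

    def effective_mismatch_positions(self) -> tuple[int, ...]:
        """Mismatch positions with unaligned read positions counted as mismatches."""
        pos = list(range(self.read_start)) + list(self.mismatches) + list(
            range(self.read_end, self.read_length)
        )
        return tuple(sorted(pos))

    def mismatches_original(self) -> tuple[int, ...]:
        """Mismatch positions in coordinates of the read as read from FASTQ."""
        if self.strand == "+":
            return tuple(sorted(self.mismatches))
        l = self.read_length
        return tuple(sorted(l - 1 - p for p in self.mismatches))


# One aligned block: (ref_start, ref_end, read_start, read_end), all half-open.
Block = tuple[int, int, int, int]


@dataclass(frozen=True)
class SplitAlignment:
    """An alignment of one read in one or more gapless blocks.

    Adjacent blocks are separated either by a reference gap (intron or
    deletion; no read bases consumed) or by a read gap (insertion; no
    reference bases consumed).  Zero-gap neighbours are disallowed - they
    must be merged into one block.
    """

    read_id: str
    rname: str
    strand: str
    blocks: tuple[Block, ...]
    mismatch_count: int
    read_length: int
    source: str = "initial"  # initial | extension | fragment | fragment-merge | local
    fragment_side: Optional[str] = None  # 'f1' | 'f2' for fragment-derived splits

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("alignment must have at least one block")
        prev = None
        for b in self.blocks:
            rs, re_, qs, qe = b
            if re_ - rs != qe - qs or re_ <= rs:
                raise ValueError(f"malformed block {b}")
            if prev is not None:
                ref_gap = rs - prev[1]
                read_gap = qs - prev[3]
                if ref_gap < 0 or read_gap < 0:
                    raise ValueError("blocks must increase on reference and read")
                if ref_gap == 0 and read_gap == 0:
                    raise ValueError("zero-gap adjacent blocks must be merged")
                if ref_gap > 0 and read_gap > 0:
                    raise ValueError("a split may gap the reference or the read, not both")
            prev = b

    @property
    def ref_start(self) -> int:
        return self.blocks[0][0]

    @property
    def ref_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def read_start(self) -> int:
        return self.blocks[0][2]

    @property
    def read_end(self) -> int:
        return self.blocks[-1][3]

    @property
    def n_clipped(self) -> int:
        return self.read_start + (self.read_length - self.read_end)

    @property
    def effective_mismatches(self) -> int:
        """Substitutions plus soft-clipped bases; the resolution order key."""
        return self.mismatch_count + self.n_clipped

    def gaps(self) -> list[tuple[int, int, int]]:
        """Per split position: (donor_end, acceptor_start, read_gap)."""
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            out.append((a[1], b[0], b[2] - a[3]))
        return out

    def gap_sizes(self) -> list[int]:
        """Signed gap sizes: reference gap, or negative read gap for insertions."""
        return [(acc - don) if rg == 0 else -rg for don, acc, rg in self.gaps()]

    def junction_key(self) -> tuple:
        """Hashable identity of this read's placement (used for de-duplication)."""
        return (self.read_id, self.rname, self.strand, self.blocks)


@dataclass(frozen=True)
class SpliceSite:
    """One splice site / gap position on the reference.

    ``read_gap`` > 0 encodes an insertion site (donor_end == acceptor_start);
    otherwise the gap spans [donor_end, acceptor_start) on the reference.
    """

    rname: str
    donor_end: int
    acceptor_start: int
    read_gap: int = 0

    @property
    def gap_size(self) -> int:
        return (self.acceptor_start - self.donor_end) if self.read_gap == 0 else -self.read_gap

    @property
    def interval(self) -> tuple[int, int]:
        return (self.donor_end, self.acceptor_start)


@dataclass
class Context:
    """A cluster of alignments on one reference within bounded genomic distance."""

    id: int
    rname: str
    start: int
    end: int
    members: list = field(default_factory=list)  # list[SplitAlignment]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """A multi-exon gene model on one reference strand."""

    name: str
    rname: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.name}: empty exon ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or out of order")
            prev_end = e

    def introns(self) -> list[tuple[int, int]]:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class IndelEvent:
    """One simulated indel, in left-aligned canonical representation.

    ``ref_pos`` is the reference coordinate where the event applies (first
    deleted base, or the base before which the insertion sits).  ``read_pos``
    is the oriented read coordinate of the first read base after the deletion
    / the first inserted base.
    """

    kind: str  # 'I' or 'D'
    ref_pos: int
    length: int
    read_pos: int


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one read."""

    read_id: str
    rname: str
    strand: str
    blocks: tuple[tuple[int, int], ...]  # reference blocks, split at ref gaps only
    mismatch_positions: tuple[int, ...] = ()  # oriented read coords
    indels: tuple[IndelEvent, ...] = ()

    def __post_init__(self):
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"truth {self.read_id}: empty block ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"truth {self.read_id}: blocks out of order")
            prev_end = e

    def junctions(self, min_intron: int = 50) -> list[tuple[int, int]]:
        """Reference gaps large enough to be introns (the rest are deletions)."""
        return [
            (a[1], b[0])
            for a, b in zip(self.blocks, self.blocks[1:])
            if b[0] - a[1] >= min_intron
        ]

    def n_junctions(self, min_intron: int = 50) -> int:
        return len(self.junctions(min_intron))


@dataclass(frozen=True)
class SamRecord:
    """One SAM alignment line (subset of fields used by this package)."""

    qname: str
    flag: int
    rname: str
    pos: int  # 0-based here; write_sam converts to 1-based
    mapq: int
    cigar: str
    seq: str
    qual: str = "*"
    tags: tuple[str, ...] = ()

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 16)
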