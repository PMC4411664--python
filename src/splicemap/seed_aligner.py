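"""Pluggable aligner contract plus the built-in seed-and-extend aligner.

The mapping pipeline only requires an aligner that (1) can index reference
sequences, (2) performs seeded alignments with adjustable seed length and
reports *every* placement whose seed matches exactly (up to ``max_hits``),
and (3) performs no gapped alignment of its own - gaps are the pipeline's
job.  The built-in aligner implements this contract with an exact k-mer
hash index and ungapped extension; external alignment programs can be
substituted by implementing :class:`AlignerContract`.

Reverse-strand placements are found by aligning the reverse complement of
the read against the forward reference; all coordinates of a '-' alignment
refer to that oriented sequence (see ``model``).
"""

from __future__ import annotations

from typing import Protocol, Sequence

from .model import AlignmentCategory, RawAlignment, Read, ReferenceSequence, revcomp


class AlignerContract(Protocol):
    """Interface an integrated short-read aligner must provide."""

    def build_index(
        self, references: Sequence[ReferenceSequence], seed_length: int
    ) -> "KmerIndex": ...

    def align_anchored(
        self,
        read: Read,
        index: "KmerIndex",
        max_mismatches: int,
        max_hits: int,
        anchor: str,
    ) -> list[RawAlignment]: ...

    def align_local(
        self, read: Read, index: "KmerIndex", min_aligned: int
    ) -> list[RawAlignment]: ...


class KmerIndex:
    """Exact k-mer index over a set of reference sequences.

    Only forward-strand k-mers are stored; a reverse-strand occurrence of a
    query is reported by looking up its reverse complement.  Lookups of any
    string of seed length return exactly the positions where it occurs.
    """

    def __init__(self, references: Sequence[ReferenceSequence], seed_length: int):
        if not 10 <= seed_length <= 30:
            raise ValueError("seed length must be in [10, 30]")
        shortest = min(len(r.sequence) for r in references)
        if seed_length > shortest:
            raise ValueError("seed length exceeds the shortest reference")
        self.seed_length = seed_length
        self.references = {r.name: r.sequence for r in references}
        self._table: dict[str, list[tuple[str, int]]] = {}
        k = seed_length
        for ref in references:
            seq = ref.sequence
            name = ref.name
            table = self._table
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue  # N matches nothing
                hits = table.get(kmer)
                if hits is None:
                    table[kmer] = [(name, pos)]
                else:
                    hits.append((name, pos))

    def lookup_forward(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand occurrences of ``kmer``: [(rname, pos)]."""
        if len(kmer) != self.seed_length:
            raise ValueError("query length must equal the seed length")
        return self._table.get(kmer, [])

    def lookup(self, kmer: str) -> list[tuple[str, str, int]]:
        """Strand-tagged occurrences: [(rname, strand, pos)].

        A '-' hit at pos means the reverse complement of ``kmer`` occurs on
        the forward strand at pos.
        """
        out = [(name, "+", pos) for name, pos in self.lookup_forward(kmer)]
        out += [(name, "-", pos) for name, pos in self.lookup_forward(revcomp(kmer))]
        return out


def build_index(
    references: Sequence[ReferenceSequence], seed_length: int
) -> KmerIndex:
    """Prepare the k-mer index of the reference set (both strands queryable)."""
    return KmerIndex(references, seed_length)


def _mismatch_positions(read: str, ref: str, ref_start: int, lo: int, hi: int) -> list[int]:
    """Oriented read positions in [lo, hi) where read and reference disagree.

    Reference N bases match nothing and always count as mismatches.
    """
    segment = ref[ref_start + lo : ref_start + hi]
    window = read[lo:hi]
    if segment == window and "N" not in segment:
        return []
    return [
        lo + i
        for i, (a, b) in enumerate(zip(window, segment))
        if a != b or b == "N"
    ]


def _extend_placement(
    read_id: str,
    oriented: str,
    rname: str,
    strand: str,
    ref: str,
    ref_start_of_read: int,
    anchor: str,
) -> RawAlignment:
    """Extend an anchored seed hit ungapped across the full read.

    The read is clipped only where it overhangs the reference boundaries;
    within bounds the alignment is end-to-end with mismatches recorded.
    """
    l = len(oriented)
    lo = max(0, -ref_start_of_read)
    hi = min(l, len(ref) - ref_start_of_read)
    mism = _mismatch_positions(oriented, ref, ref_start_of_read, lo, hi)
    return RawAlignment(
        read_id=read_id,
        rname=rname,
        strand=strand,
        ref_start=ref_start_of_read + lo,
        read_start=lo,
        read_end=hi,
        read_length=l,
        mismatches=tuple(mism),
        end_to_end=(lo == 0 and hi == l),
        seed_anchor=anchor,
    )


def align_anchored(
    read: Read,
    index: KmerIndex,
    max_mismatches: int,
    max_hits: int = 10,
    anchor: str = "start",
) -> list[RawAlignment]:
    """Seeded, ungapped alignment of a read anchored at its start or end.

    The seed (first or last ``seed_length`` bases) must match the reference
    exactly; every seed hit is extended across the full read and retained,
    up to ``max_hits`` per strand orientation.  ``max_mismatches`` is not a
    filter here - raw alignments keep their mismatch positions and are
    categorised downstream - but wildly mismatched placements beyond any
    category's use (more than the read length) never arise by construction.
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    k = index.seed_length
    l = len(read.sequence)
    if l < k:
        return []
    out: list[RawAlignment] = []
    for strand in ("+", "-"):
        oriented = read.sequence if strand == "+" else revcomp(read.sequence)
        if anchor == "start":
            seed = oriented[:k]
            offset = 0
        else:
            seed = oriented[-k:]
            offset = l - k
        hits = index.lookup_forward(seed)
        if len(hits) > max_hits:
            hits = sorted(hits)[:max_hits]
        for rname, pos in hits:
            ref = index.references[rname]
            out.append(
                _extend_placement(
                    read.id, oriented, rname, strand, ref, pos - offset, anchor
                )
            )
    out.sort(key=lambda a: (a.rname, a.ref_start, a.strand))
    return out


def align_local(
    read: Read,
    index: KmerIndex,
    min_aligned: int,
    flank_mismatches: int = 2,
    max_hits: int = 10,
    stride: int = 2,
) -> list[RawAlignment]:
    """Maximal ungapped local blocks of the read against the reference.

    Locality is emulated by seeding every ``stride`` read offsets and
    extending each exact seed hit in both directions, tolerating up to
    ``flank_mismatches`` substitutions per flank; blocks are trimmed to end
    on matching bases.  Only blocks of length >= ``min_aligned`` are
    reported.
    """
    k = index.seed_length
    l = len(read.sequence)
    if l < k or min_aligned < k:
        min_aligned = max(min_aligned, k)
    out: list[RawAlignment] = []
    for strand in ("+", "-"):
        oriented = read.sequence if strand == "+" else revcomp(read.sequence)
        seen: set = set()
        seen_diag: set[tuple[str, int]] = set()
        offsets = list(range(0, l - k + 1, max(1, stride)))
        if offsets and offsets[-1] != l - k:
            offsets.append(l - k)
        for off in offsets:
            seed = oriented[off : off + k]
            for rname, pos in index.lookup_forward(seed):
                ref = index.references[rname]
                diag = pos - off  # ref position of read offset 0
                if (rname, diag) in seen_diag:
                    continue
                seen_diag.add((rname, diag))
                qs, qe = _extend_local(oriented, ref, diag, off, off + k, flank_mismatches)
                if qe - qs < min_aligned:
                    continue
                key = (rname, diag, qs, qe)
                if key in seen:
                    continue
                seen.add(key)
                mism = _mismatch_positions(oriented, ref, diag, qs, qe)
                out.append(
                    RawAlignment(
                        read_id=read.id,
                        rname=rname,
                        strand=strand,
                        ref_start=diag + qs,
                        read_start=qs,
                        read_end=qe,
                        read_length=l,
                        mismatches=tuple(mism),
                        end_to_end=(qs == 0 and qe == l),
                        # one-sided locals behave like anchored candidates:
                        # the unaligned part sits opposite the aligned end
                        seed_anchor="start" if qs == 0 else "end",
                    )
                )
    # keep the longest blocks first, bounded per read
    out.sort(key=lambda a: (-(a.read_end - a.read_start), a.rname, a.ref_start, a.strand))
    dedup: list[RawAlignment] = []
    covered: set[tuple[str, str, int, int, int]] = set()
    for a in out:
        key = (a.rname, a.strand, a.ref_start - a.read_start, a.read_start, a.read_end)
        if key in covered:
            continue
        covered.add(key)
        dedup.append(a)
    dedup.sort(key=lambda a: (a.rname, a.ref_start, a.strand, a.read_start))
    return dedup[: 4 * max_hits]


def _extend_local(
    read: str, ref: str, diag: int, qs: int, qe: int, budget: int
) -> tuple[int, int]:
    """Extend [qs, qe) along one diagonal; trim so the block ends on matches."""
    l = len(read)
    # right
    miss = 0
    last_good = qe
    j = qe
    while j < l and diag + j < len(ref):
        if read[j] == ref[diag + j] and ref[diag + j] != "N":
            j += 1
            last_good = j
        else:
            miss += 1
            if miss > budget:
                break
            j += 1
    qe = last_good
    # left
    miss = 0
    first_good = qs
    j = qs - 1
    while j >= 0 and diag + j >= 0:
        if read[j] == ref[diag + j] and ref[diag + j] != "N":
            first_good = j
            j -= 1
        else:
            miss += 1
            if miss > budget:
                break
            j -= 1
    return first_good, qe


def classify(
    raw: RawAlignment, max_mismatches: int, end_distance: int
) -> AlignmentCategory:
    """Four-way classification of a raw alignment.

    FULL: end-to-end with at most ``max_mismatches`` substitutions.
    CANDIDATE_MULTI_SPLIT: local placement with both a prefix and a suffix of
    the read unaligned.
    CANDIDATE_SINGLE_SPLIT / PARTIAL: too many mismatches (unaligned read
    positions counted as mismatches); the last allowed mismatch lies at
    least / less than ``end_distance`` from the far end of the alignment.
    The far end is the read's 3' side for a start-anchored seed and the 5'
    side for an end-anchored seed.
    """
    m = max_mismatches
    if raw.end_to_end and len(raw.mismatches) <= m:
        return AlignmentCategory.FULL
    if raw.read_start > 0 and raw.read_end < raw.read_length:
        return AlignmentCategory.CANDIDATE_MULTI_SPLIT
    eff = raw.effective_mismatch_positions()
    if len(eff) <= m:
        # clipped at a reference boundary but within budget: treat as full
        return AlignmentCategory.FULL
    if raw.seed_anchor == "start":
        last_allowed = eff[m - 1] if m > 0 else -1
        distance = (raw.read_length - 1) - last_allowed
    else:
        last_allowed = eff[-m] if m > 0 else raw.read_length
        distance = last_allowed
    if distance >= end_distance:
        return AlignmentCategory.CANDIDATE_SINGLE_SPLIT
    return AlignmentCategory.PARTIAL


_COMPLETION_SLOP = 8  # bases past the junction can match the intron by chance


def completion_boundary(raw: RawAlignment, max_mismatches: int) -> tuple[int, int]:
    """Read interval [lo, hi) to re-align for a single-split candidate.

    For a start-anchored candidate this is everything from the first
    mismatch to the read end (the true split point can precede any of the
    mismatches, so the whole mismatched tail is offered to the window
    re-alignment; the split point itself is optimised later).  A few extra
    bases on the anchored side cover junctions whose first intronic bases
    match the read by chance.  End-anchored candidates use the mirrored
    prefix.
    """
    eff = raw.effective_mismatch_positions()
    if raw.seed_anchor == "start":
        lo = eff[0] if eff else raw.read_end
        return max(raw.read_start, lo - _COMPLETION_SLOP), raw.read_length
    hi = (eff[-1] + 1) if eff else raw.read_start
    return 0, min(raw.read_end, hi + _COMPLETION_SLOP)


class BuiltinAligner:
    """The built-in exact-seed aligner, packaged behind the plug-in contract."""

    def build_index(self, references, seed_length):
        return build_index(references, seed_length)

    def align_anchored(self, read, index, max_mismatches, max_hits=10, anchor="start"):
        return align_anchored(read, index, max_mismatches, max_hits, anchor)

    def align_local(self, read, index, min_aligned, flank_mismatches=2, max_hits=10, stride=2):
        return align_local(read, index, min_aligned, flank_mismatches, max_hits, stride)
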