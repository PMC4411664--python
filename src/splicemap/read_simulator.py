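"""Ground-truth read simulator: random genome, gene models, spliced reads.

The generator emulates a compact, gene-dense genome: multi-exon genes with
short introns, transcripts sampled on both strands, and single-end reads
carrying substitution errors, small indels (1-10 nt) and 0-3 splice
junctions per read.  Every read comes with a truth record (reference blocks,
mismatch positions, indel events) that drives all evaluation.

Two properties keep ground truth and mapping coordinate-comparable:

* generated introns carry canonical splice motifs (GT..AG on the forward
  strand, CT..AC for reverse-strand genes), written into the genome at
  generation time, so junction coordinates are not shift-ambiguous;
* recorded indels are left-aligned, the canonical representation a mapper's
  leftmost tie-break produces.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .model import GeneModel, IndelEvent, Read, ReferenceSequence, TruthRecord, revcomp

_BASES = np.array(list("ACGT"))
_ALT = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def simulate_genome(
    length: int, gc: float = 0.5, seed: int = 0, name: str = "chr1"
) -> ReferenceSequence:
    """Random genome of the given length and GC content (deterministic per seed)."""
    if length < 10_000:
        raise ValueError("genome length must be at least 10,000 nt")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return ReferenceSequence(name, seq)


def simulate_genes(
    genome: ReferenceSequence,
    n_genes: int,
    seed: int = 0,
    exon_count_range: tuple[int, int] = (4, 8),
    exon_length_range: tuple[int, int] = (80, 220),
    short_exon_range: tuple[int, int] = (22, 36),
    intron_length_range: tuple[int, int] = (60, 900),
    intergenic_range: tuple[int, int] = (2_000, 6_000),
) -> tuple[list[GeneModel], ReferenceSequence]:
    """Place non-overlapping gene models and write splice motifs into the genome.

    Each gene with at least five exons gets two adjacent short internal exons
    (hosts for multi-junction reads).  Returns the models and the genome with
    canonical intron motifs written at every generated junction.
    """
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    glen = len(seq)
    models: list[GeneModel] = []
    cursor = int(rng.integers(*intergenic_range))
    for gi in range(n_genes):
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_lens = []
        for ei in range(n_exons):
            if n_exons >= 5 and ei in (2, 3):
                exon_lens.append(int(rng.integers(short_exon_range[0], short_exon_range[1] + 1)))
            else:
                exon_lens.append(int(rng.integers(exon_length_range[0], exon_length_range[1] + 1)))
        intron_lens = [
            int(rng.integers(intron_length_range[0], intron_length_range[1] + 1))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for ei, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if ei < n_exons - 1:
                pos += intron_lens[ei]
        if pos >= glen - intergenic_range[1]:
            raise ValueError(
                f"genome too small for {n_genes} genes (ran out of space at gene {gi})"
            )
        model = GeneModel(f"gene{gi:03d}", genome.name, strand, tuple(exons))
        models.append(model)
        for istart, iend in model.introns():
            if strand == "+":
                seq[istart], seq[istart + 1] = "G", "T"
                seq[iend - 2], seq[iend - 1] = "A", "G"
            else:
                seq[istart], seq[istart + 1] = "C", "T"
                seq[iend - 2], seq[iend - 1] = "A", "C"
        cursor = pos + int(rng.integers(*intergenic_range))
    return models, ReferenceSequence(genome.name, "".join(seq))


def annotation_rows(models: Sequence[GeneModel]) -> list[tuple[str, str, int, int]]:
    """Annotation-table rows (chrom, strand, intron_start, intron_end)."""
    rows = []
    for m in models:
        for s, e in m.introns():
            rows.append((m.rname, m.strand, s, e))
    return rows


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

_EVENT_SEPARATION = 12  # min read distance between two indel events
_EVENT_MARGIN = 2       # min read distance of an event from read ends / block edges


def _placements(
    models: Sequence[GeneModel], read_length: int, k: int, min_anchor: int
) -> list[tuple[int, int, int, int]]:
    """Feasible placements for a read spanning exactly k junctions.

    Returns (gene index, first exon index, x_lo, x_hi) with x the number of
    read bases in the first spanned exon.
    """
    out = []
    l = read_length
    for gi, m in enumerate(models):
        lens = [e - s for s, e in m.exons]
        if k == 0:
            for ei, el in enumerate(lens):
                if el >= l:
                    out.append((gi, ei, 0, el - l))
            continue
        for a in range(len(lens) - k):
            mid = sum(lens[a + 1 : a + k])
            if mid > l - 2 * min_anchor:
                continue
            x_lo = max(min_anchor, l - mid - lens[a + k])
            x_hi = min(lens[a], l - mid - min_anchor)
            if x_lo <= x_hi:
                out.append((gi, a, x_lo, x_hi))
    return out


class IndelLocus:
    """A genomic indel polymorphism: shared by every read covering it."""

    __slots__ = ("kind", "ref_pos", "length", "inserted")

    def __init__(self, kind: str, ref_pos: int, length: int, inserted: str = ""):
        self.kind = kind
        self.ref_pos = ref_pos
        self.length = length
        self.inserted = inserted

    def __repr__(self):
        return f"IndelLocus({self.kind}, {self.ref_pos}, {self.length})"


def simulate_indel_loci(
    models: Sequence[GeneModel],
    genome: ReferenceSequence,
    indel_rate: float,
    rng: np.random.Generator,
    max_size: int = 10,
) -> dict[int, list[IndelLocus]]:
    """Place indel polymorphisms inside exons, one set per gene.

    ``indel_rate`` is the per-transcribed-base probability of a locus.
    Loci keep a margin from exon boundaries, are separated by at least
    a read-event spacing, and are recorded left-aligned (the canonical
    representation a mapper's leftmost tie-break produces).
    """
    gseq = genome.sequence
    out: dict[int, list[IndelLocus]] = {}
    for gi, m in enumerate(models):
        loci: list[IndelLocus] = []
        last = -(10**9)
        for s, e in m.exons:
            pos = s + 4
            while pos < e - max_size - 4:
                if pos - last >= _EVENT_SEPARATION and rng.random() < indel_rate:
                    size = int(rng.integers(1, max_size + 1))
                    if rng.random() < 0.5:
                        ins = "".join(rng.choice(_BASES, size=size))
                        r = pos
                        # left-align: rotate while the base before the site
                        # equals the last inserted base
                        while r > s + 2 and gseq[r - 1] == ins[-1]:
                            ins = gseq[r - 1] + ins[:-1]
                            r -= 1
                        loci.append(IndelLocus("I", r, size, ins))
                    else:
                        r = pos
                        while r > s + 2 and gseq[r - 1] == gseq[r + size - 1]:
                            r -= 1
                        if r + size <= e - 2:
                            loci.append(IndelLocus("D", r, size))
                    last = pos
                    pos += _EVENT_SEPARATION
                else:
                    pos += 1
        out[gi] = sorted(loci, key=lambda v: v.ref_pos)
    return out


def _walk_read(
    genome: str,
    segments: list[tuple[int, int]],
    read_length: int,
    mismatch_rate: float,
    loci: Sequence[IndelLocus],
    rng: np.random.Generator,
) -> Optional[tuple[str, tuple, tuple, tuple]]:
    """Generate one read along the given reference segments.

    Returns (sequence, blocks, mismatch positions, indel events) in walk
    (oriented) coordinates, or None when the attempt violated a constraint
    (an indel locus too close to the read end, or the transcript ran out)
    and should be retried.  ``segments`` must extend through the remaining
    exons of the gene: a deletion consumes extra transcript bases, so the
    walk may spill across the next junction (never into an intron).
    """
    l = read_length
    by_pos = {v.ref_pos: v for v in loci}
    chars: list[str] = []
    blocks: list[list[int]] = []
    events: list[IndelEvent] = []
    seg_idx = 0
    seg_start, seg_end = segments[0]
    ref_pos = seg_start
    # a read may not start inside deleted bases
    for v in loci:
        if v.kind == "D" and v.ref_pos < ref_pos < v.ref_pos + v.length:
            return None
    blocks.append([ref_pos, ref_pos])
    p = 0
    while p < l:
        locus = by_pos.get(ref_pos)
        if locus is not None:
            if locus.kind == "D":
                if p == 0:
                    # the read starts right after the deleted bases: no event
                    ref_pos += locus.length
                    blocks[-1] = [ref_pos, ref_pos]
                    continue
                if p < _EVENT_MARGIN or p > l - _EVENT_MARGIN:
                    return None
                blocks[-1][1] = ref_pos
                events.append(IndelEvent("D", ref_pos, locus.length, p))
                ref_pos += locus.length
                blocks.append([ref_pos, ref_pos])
                continue
            if p == 0:
                # insertion precedes the read start: not part of this read
                pass
            else:
                if p < _EVENT_MARGIN or p + locus.length > l - _EVENT_MARGIN:
                    return None
                chars.extend(locus.inserted)
                events.append(IndelEvent("I", ref_pos, locus.length, p))
                p += locus.length
            # fall through to consume the reference base at ref_pos
        chars.append(genome[ref_pos])
        ref_pos += 1
        p += 1
        blocks[-1][1] = ref_pos
        if ref_pos == seg_end and p < l:
            seg_idx += 1
            if seg_idx >= len(segments):
                return None  # transcript exhausted before the read was full
            seg_start, seg_end = segments[seg_idx]
            ref_pos = seg_start
            blocks.append([ref_pos, ref_pos])
    if any(b[1] - b[0] < 1 for b in blocks):
        return None
    # substitution errors (never inside inserted segments; those bases are
    # shared polymorphism sequence, not part of the reference)
    inserted = set()
    for ev in events:
        if ev.kind == "I":
            inserted.update(range(ev.read_pos, ev.read_pos + ev.length))
    mism: list[int] = []
    if mismatch_rate > 0:
        hits = np.nonzero(rng.random(l) < mismatch_rate)[0]
        for p3 in hits:
            p3 = int(p3)
            if p3 in inserted:
                continue
            chars[p3] = _ALT[chars[p3]][int(rng.integers(0, 3))]
            mism.append(p3)
    return (
        "".join(chars),
        tuple((b[0], b[1]) for b in blocks),
        tuple(mism),
        tuple(sorted(events, key=lambda e: e.read_pos)),
    )


def simulate_reads(
    models: Sequence[GeneModel],
    genome: ReferenceSequence,
    read_length: int = 76,
    n_reads: Optional[int] = None,
    coverage: Optional[float] = None,
    mismatch_rate: float = 0.0,
    indel_rate: float = 0.0,
    multi_junction_weights: Optional[dict[int, float]] = None,
    seed: int = 0,
    min_anchor: int = 1,
) -> tuple[list[Read], list[TruthRecord]]:
    """Simulate single-end reads from spliced transcripts, with ground truth.

    Reads are drawn uniformly over the feasible placements for their junction
    count; the junction count per read follows ``multi_junction_weights``
    (default {0: 0.7, 1: 0.25, 2: 0.04, 3: 0.01}).  ``min_anchor`` is the
    minimum number of read bases on each side of the outermost junctions
    (default 1).  ``mismatch_rate`` is the per-read, per-base substitution
    error probability; ``indel_rate`` is the per-transcribed-base probability
    of an indel *polymorphism locus* - a genomic variant carried by every
    read covering it, which is what lets coverage pinpoint indel positions.
    """
    if not 0 <= mismatch_rate <= 1 or not 0 <= indel_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    if multi_junction_weights is None:
        multi_junction_weights = {0: 0.7, 1: 0.25, 2: 0.04, 3: 0.01}
    if n_reads is None:
        if coverage is None:
            raise ValueError("provide n_reads or coverage")
        total = sum(m.transcript_length() for m in models)
        n_reads = max(1, math.ceil(coverage * total / read_length))
    rng = np.random.default_rng(seed)
    ks = sorted(k for k, w in multi_junction_weights.items() if w > 0)
    weights = np.array([multi_junction_weights[k] for k in ks], dtype=float)
    weights = weights / weights.sum()
    placements = {k: _placements(models, read_length, k, min_anchor) for k in ks}
    for k in ks:
        if not placements[k]:
            raise ValueError(f"no gene model admits a read with {k} junctions")
    gseq = genome.sequence
    loci = simulate_indel_loci(models, genome, indel_rate, rng)
    reads: list[Read] = []
    truths: list[TruthRecord] = []
    draws = rng.choice(len(ks), size=n_reads, p=weights)
    for ri in range(n_reads):
        k = ks[int(draws[ri])]
        rid = f"r{ri:06d}"
        for _attempt in range(80):
            gi, a, x_lo, x_hi = placements[k][int(rng.integers(0, len(placements[k])))]
            model = models[gi]
            exons = model.exons
            # segments run through the remaining exons so a deletion near a
            # junction spills into the next exon, exactly as a transcript does
            if k == 0:
                s = exons[a][0] + int(rng.integers(x_lo, x_hi + 1))
                segments = [(s, exons[a][1])] + list(exons[a + 1 :])
            else:
                x = int(rng.integers(x_lo, x_hi + 1))
                segments = [(exons[a][1] - x, exons[a][1])] + list(exons[a + 1 :])
            result = _walk_read(gseq, segments, read_length, mismatch_rate, loci[gi], rng)
            if result is None:
                continue
            seq, blocks, mism, indels = result
            # the walk must span at least the k planned junctions (deletions
            # may have spilled it across one more)
            n_junc = sum(1 for x1, x2 in zip(blocks, blocks[1:]) if x2[0] - x1[1] >= 50)
            if n_junc < k or (n_junc > k and not indels):
                continue
            fastq_seq = seq if model.strand == "+" else revcomp(seq)
            reads.append(Read(rid, fastq_seq, "I" * read_length))
            truths.append(
                TruthRecord(rid, model.rname, model.strand, blocks, mism, indels)
            )
            break
        else:
            raise RuntimeError(f"could not generate read {rid} after 80 attempts")
    return reads, truths
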