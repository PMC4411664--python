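"""Local and global resolution of multi-mapped reads.

This stage turns the pool of alternative alignments produced by seeding,
window completion and context extension into at most one alignment per read:

1. splice sites are scored by the evidence score
   ``evidence = sum_i w^i * n_i`` (n_i = distinct reads with i mismatches
   supporting the site, default w = 0.3);
2. within each group of overlapping sites only the three best-supported
   sites are retained and split alignments using discarded sites are dropped
   (falling back to their best surviving alternative, if any);
3. fragment-derived single-splits of the same read are merged into
   multi-split alignments (internal exons must be at least the minimum exon
   size);
4. per context, each read's alignment with the largest support score - a
   weighted coverage measure in and around the alignment - is chosen
   (local resolution), and the same argmax is applied across
   contexts after recomputing support from the per-context choices (global
   resolution).

Gap-size classification (insertion / deletion / intron) is applied when
preparing the final output; split alignments whose gaps fall outside all
three legal ranges are never created upstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import Context, GapType, SplitAlignment, SpliceSite
from .params import MappingParams


# ---------------------------------------------------------------------------
# Gap classification
# ---------------------------------------------------------------------------

def classify_gap(
    gap_size: int,
    max_ins: int = 10,
    max_del: int = 10,
    min_intron: int = 50,
    max_intron: int = 300_000,
) -> Optional[GapType]:
    """Classify a signed gap size, or return None for illegal sizes.

    Negative gaps of magnitude <= ``max_ins`` are insertions, gaps in
    [1, max_del] deletions, gaps in [min_intron, max_intron] introns
    (all boundaries inclusive).  A zero gap is an error: adjacent blocks
    with no gap must have been merged.
    """
    if gap_size == 0:
        raise ValueError("zero gap: adjacent blocks must be merged")
    if gap_size < 0:
        return GapType.INSERTION if -gap_size <= max_ins else None
    if gap_size <= max_del:
        return GapType.DELETION
    if min_intron <= gap_size <= max_intron:
        return GapType.INTRON
    return None


def legal_gap(gap_size: int, params: MappingParams) -> bool:
    if gap_size == 0:
        return False
    return (
        classify_gap(
            gap_size,
            params.max_insertion,
            params.max_deletion,
            params.min_intron,
            params.max_intron,
        )
        is not None
    )


# ---------------------------------------------------------------------------
# Evidence score (splice-site support, Eq.-style weighted count)
# ---------------------------------------------------------------------------

def count_block_mismatches(oriented: str, ref: str, blocks) -> int:
    """Substitutions of an alignment's blocks against the reference.

    Reference N bases match nothing and always count as substitutions.
    """
    subs = 0
    for rs, re_, qs, qe in blocks:
        seg = ref[rs:re_]
        win = oriented[qs:qe]
        if seg != win or "N" in seg:
            subs += sum(1 for a, b in zip(win, seg) if a != b or b == "N")
    return subs


def evidence_score(counts: Sequence[int], w: float) -> float:
    """Weighted support of a splice site: sum over i of w**i * n_i.

    ``counts[i]`` is the number of distinct reads supporting the site with i
    mismatches; higher-mismatch supporters are down-weighted geometrically.
    """
    if not (0.0 < w < 1.0):
        raise ValueError("w must be in (0, 1)")
    total = 0.0
    weight = 1.0
    for n in counts:
        if n < 0:
            raise ValueError("support counts must be non-negative")
        total += weight * n
        weight *= w
    return total


def annotation_bonus(
    site: SpliceSite,
    evidence: float,
    annotation: Optional[set[tuple[str, int, int]]],
    bonus: float,
) -> float:
    """Add ``bonus`` to a site's evidence when its intron is annotated."""
    if bonus < 0:
        raise ValueError("annotation bonus must be >= 0")
    if annotation and (site.rname, site.donor_end, site.acceptor_start) in annotation:
        return evidence + bonus
    return evidence


# ---------------------------------------------------------------------------
# Site collection and selection
# ---------------------------------------------------------------------------

def collect_sites(
    alignments: Iterable[SplitAlignment], max_mismatches: int
) -> dict[SpliceSite, list[int]]:
    """Tally per-site support counts n_0..n_m over distinct reads.

    A read supports a site with i mismatches if its best (fewest-mismatch)
    alignment variant using the site has i substitutions.
    """
    best: dict[tuple[SpliceSite, str], int] = {}
    for a in alignments:
        for donor_end, acceptor_start, read_gap in a.gaps():
            site = SpliceSite(a.rname, donor_end, acceptor_start, max(read_gap, 0))
            key = (site, a.read_id)
            mm = min(a.mismatch_count, max_mismatches)
            if key not in best or mm < best[key]:
                best[key] = mm
    counts: dict[SpliceSite, list[int]] = {}
    for (site, _rid), mm in best.items():
        counts.setdefault(site, [0] * (max_mismatches + 1))[mm] += 1
    return counts


def sites_overlap(a: SpliceSite, b: SpliceSite) -> bool:
    """Whether two sites overlap: intron intervals intersect or a donor or
    acceptor coordinate is shared.  Insertion sites have zero-length
    intervals; sharing the coordinate still links them."""
    if a.rname != b.rname:
        return False
    if a.donor_end == b.donor_end or a.acceptor_start == b.acceptor_start:
        return True
    lo = max(a.donor_end, b.donor_end)
    hi = min(a.acceptor_start, b.acceptor_start)
    return lo < hi


def select_best_sites(
    site_counts: dict[SpliceSite, list[int]],
    w: float,
    annotation: Optional[set[tuple[str, int, int]]] = None,
    bonus: float = 1.0,
    keep: int = 3,
) -> set[SpliceSite]:
    """Resolve overlapping sites: keep each site unless at least ``keep``
    directly overlapping sites carry better evidence.

    The overlap relation is applied pairwise, not transitively: false intron
    intervals can be hundreds of kilobases long, and chaining components
    through them would pit distant, unrelated sites against each other.
    Ties are broken towards the leftmost donor, then leftmost acceptor.
    """
    scores = {
        s: annotation_bonus(s, evidence_score(c, w), annotation, bonus)
        for s, c in site_counts.items()
    }

    def rank(s: SpliceSite):
        return (-scores[s], s.donor_end, s.acceptor_start, s.read_gap)

    order = sorted(site_counts, key=lambda s: (s.rname, s.donor_end, s.acceptor_start))
    retained: set[SpliceSite] = set()
    for s in order:
        my_rank = rank(s)
        better = 0
        for o in order:
            if o is s or not sites_overlap(o, s):
                continue
            if rank(o) < my_rank:
                better += 1
                if better >= keep:
                    break
        if better < keep:
            retained.add(s)
    return retained


def uses_only_sites(a: SplitAlignment, retained: set[SpliceSite]) -> bool:
    for donor_end, acceptor_start, read_gap in a.gaps():
        site = SpliceSite(a.rname, donor_end, acceptor_start, max(read_gap, 0))
        if site not in retained:
            return False
    return True


# ---------------------------------------------------------------------------
# Support score
# ---------------------------------------------------------------------------

@dataclass
class SupportScore:
    value: float
    components: tuple[float, float, float]  # (upstream max, body max, downstream max)


class CoverageProfile:
    """Per-base read depth over a context span, one count per distinct read."""

    def __init__(self, rname: str, start: int, end: int):
        self.rname = rname
        self.start = start
        self.end = max(end, start + 1)
        self._diff = np.zeros(self.end - self.start + 1, dtype=np.int32)
        self._cov: Optional[np.ndarray] = None

    @classmethod
    def from_alignments(
        cls, rname: str, start: int, end: int, alignments: Iterable[SplitAlignment]
    ) -> "CoverageProfile":
        prof = cls(rname, start, end)
        for a in alignments:
            prof.add(a)
        return prof

    def add(self, a: SplitAlignment) -> None:
        self._cov = None
        n = len(self._diff)
        for rs, re_, _qs, _qe in a.blocks:
            lo = min(max(rs - self.start, 0), n - 1)
            hi = min(max(re_ - self.start, 0), n - 1)
            self._diff[lo] += 1
            self._diff[hi] -= 1

    @property
    def coverage(self) -> np.ndarray:
        if self._cov is None:
            self._cov = np.cumsum(self._diff[:-1])
        return self._cov

    def max_in(self, lo: int, hi: int) -> float:
        cov = self.coverage
        lo = max(lo - self.start, 0)
        hi = min(hi - self.start, len(cov))
        if hi <= lo:
            return 0.0
        return float(cov[lo:hi].max())

    def sum_in(self, lo: int, hi: int) -> float:
        """Total coverage over [lo, hi); positions outside the profile count 0."""
        cov = self.coverage
        clo = max(lo - self.start, 0)
        chi = min(hi - self.start, len(cov))
        if chi <= clo:
            return 0.0
        return float(cov[clo:chi].sum())

    def mean_in(self, lo: int, hi: int) -> float:
        """Mean coverage over [lo, hi); positions outside the profile count 0."""
        if hi <= lo:
            return 0.0
        return self.sum_in(lo, hi) / (hi - lo)


def support_score(
    alignment: SplitAlignment, profile: CoverageProfile, params: MappingParams
) -> SupportScore:
    """Weighted sum of maximum coverages in and around the alignment.

    Body term: the coverage mass under the aligned blocks divided by the
    read length, i.e. the average per-read-base support of the placement -
    it measures how much of the read is placed inside genuine coverage, so
    clipped or truncated alternatives and blocks overhanging into uncovered
    sequence score lower, and split blocks in one pile are not double
    counted.  Flank terms: mean coverage in the W-nt windows
    upstream/downstream of the *projected read extent* (aligned span plus
    any soft-clipped overhang); the mean keeps a window that barely grazes
    a neighbouring exon's pile from dominating the body term, and the
    projection keeps a heavily clipped variant from harvesting flank support
    out of the pile its own unaligned tail belongs to.
    """
    w = params.support_window
    l = alignment.read_length
    mass = sum(profile.sum_in(rs, re_) for rs, re_, _qs, _qe in alignment.blocks)
    # inserted read bases are supported by the coverage at the insertion site,
    # otherwise an insertion variant always trails the same placement with the
    # inserted bases absorbed as mismatches by one reference base of coverage
    for donor_end, _acc, read_gap in alignment.gaps():
        if read_gap > 0:
            mass += read_gap * profile.max_in(donor_end - 1, donor_end + 1)
    body = mass / l
    proj_start = alignment.ref_start - alignment.read_start
    proj_end = alignment.ref_end + (alignment.read_length - alignment.read_end)
    up = profile.mean_in(proj_start - w, proj_start)
    down = profile.mean_in(proj_end, proj_end + w)
    value = (
        params.support_lambda_in * body
        + params.support_lambda_flank * up
        + params.support_lambda_flank * down
    )
    return SupportScore(value=value, components=(up, body, down))


def trim_terminal_blocks(
    oriented: str,
    ref: str,
    blocks,
    max_mismatches: int,
    min_len: int,
    trim_last: bool,
) -> Optional[tuple]:
    """Shrink one terminal block until the total substitutions fit the budget.

    The trimmed block ends on a matching base and must keep ``min_len``
    aligned bases; returns None when that is impossible.
    """
    if trim_last:
        fixed = blocks[:-1]
        rs, re_, qs, qe = blocks[-1]
    else:
        fixed = blocks[1:]
        rs, re_, qs, qe = blocks[0]
    budget = max_mismatches - count_block_mismatches(oriented, ref, fixed)
    if budget < 0:
        return None
    diag = rs - qs
    if trim_last:
        subs = 0
        good = qs
        q = qs
        while q < qe:
            r = diag + q
            if oriented[q] != ref[r] or ref[r] == "N":
                subs += 1
                if subs > budget:
                    break
            else:
                good = q + 1
            q += 1
        if good - qs < min_len:
            return None
        return fixed + ((rs, diag + good, qs, good),)
    subs = 0
    good = qe
    q = qe - 1
    while q >= qs:
        r = diag + q
        if oriented[q] != ref[r] or ref[r] == "N":
            subs += 1
            if subs > budget:
                break
        else:
            good = q
        q -= 1
    if qe - good < min_len:
        return None
    return ((diag + good, re_, good, qe),) + fixed


# ---------------------------------------------------------------------------
# Fragment merging
# ---------------------------------------------------------------------------

def merge_fragment_splits(
    f1: SplitAlignment,
    f2: SplitAlignment,
    oriented: str,
    ref: str,
    params: MappingParams,
) -> Optional[SplitAlignment]:
    """Merge a left-junction and a right-junction fragment split of one read.

    The two splits must share the middle block placement (same diagonal on
    the same reference) and leave an internal exon of at least the minimum
    exon size; mismatches are recounted on the merged structure.  An
    inconsistent overlap yields no merge.
    """
    if f1.rname != f2.rname or f1.strand != f2.strand:
        return None
    if f1.read_id != f2.read_id:
        raise ValueError("fragments of different reads cannot be merged")
    if len(f1.gaps()) != 1 or len(f2.gaps()) != 1:
        return None
    # middle block: f1's right block and f2's left block must lie on one diagonal
    b1 = f1.blocks[-1]
    b2 = f2.blocks[0]
    if b1[0] - b1[2] != b2[0] - b2[2]:
        return None
    s1 = b1[2]  # read coord of the left junction
    s2 = b2[3]  # read coord of the right junction
    if s2 <= s1:
        return None
    diag_mid = b1[0] - b1[2]
    # an internal block bounded by two introns is an internal exon and must
    # be at least the minimum exon size; indel-bounded pieces only need bases
    left_gap = f1.gaps()[0][1] - f1.gaps()[0][0]
    right_gap = f2.gaps()[0][1] - f2.gaps()[0][0]
    if (
        left_gap >= params.min_intron
        and right_gap >= params.min_intron
        and s2 - s1 < params.min_exon
    ):
        return None  # internal exon too short
    left = f1.blocks[0]
    right = f2.blocks[-1]
    blocks = (
        left,
        (diag_mid + s1, diag_mid + s2, s1, s2),
        right,
    )
    try:
        merged = SplitAlignment(
            read_id=f1.read_id,
            rname=f1.rname,
            strand=f1.strand,
            blocks=blocks,
            mismatch_count=count_block_mismatches(oriented, ref, blocks),
            read_length=f1.read_length,
            source="fragment-merge",
        )
    except ValueError:
        return None
    if merged.mismatch_count > params.max_mismatches:
        return None
    for g in merged.gap_sizes():
        if not legal_gap(g, params):
            return None
    return merged


# ---------------------------------------------------------------------------
# Local and global resolution
# ---------------------------------------------------------------------------

def _tie_key(a: SplitAlignment) -> tuple:
    return (a.effective_mismatches, len(a.blocks), a.ref_start, a.rname)


def representative(variants: Sequence[SplitAlignment]) -> SplitAlignment:
    """Deterministic minimum-mismatch representative of a read's variants."""
    return min(variants, key=_tie_key)


def resolve_local(
    context: Context, params: MappingParams
) -> dict[str, SplitAlignment]:
    """Choose, per read present in the context, the best-supported alignment.

    The coverage profile counts each read once (its minimum-mismatch
    variant); each variant is then scored and the per-read argmax is taken,
    with deterministic tie-breaking (fewer mismatches, fewer blocks,
    leftmost start, reference name).
    """
    by_read: dict[str, list[SplitAlignment]] = defaultdict(list)
    for a in context.members:
        by_read[a.read_id].append(a)
    profile = CoverageProfile.from_alignments(
        context.rname,
        context.start - params.support_window,
        context.end + params.support_window,
        (representative(v) for v in by_read.values()),
    )
    chosen: dict[str, SplitAlignment] = {}
    for rid in sorted(by_read):
        scored = [
            (support_score(a, profile, params).value, a) for a in by_read[rid]
        ]
        chosen[rid] = _argmax_support(scored, params)
    return chosen


def _argmax_support(
    scored: list[tuple[float, SplitAlignment]], params: MappingParams
) -> SplitAlignment:
    """Best-supported alignment; near-ties fall through to the mismatch cascade.

    Support scores within ``support_tie_tolerance`` (relative) of the maximum
    count as equal: per-base coverage jitter between almost identical
    placements must not override the mismatch count.
    """
    best = max(s for s, _a in scored)
    floor = best * (1.0 - params.support_tie_tolerance)
    contenders = [a for s, a in scored if s >= floor]
    return min(contenders, key=_tie_key)


def resolve_global(
    contexts: Sequence[Context],
    local_choices: Sequence[dict[str, SplitAlignment]],
    params: MappingParams,
) -> dict[str, SplitAlignment]:
    """Resolve reads chosen in several contexts down to one alignment each.

    Support scores are recomputed from the per-context chosen alignments
    only, then the per-read argmax across contexts is taken with the same
    tie rules as local resolution.
    """
    profiles = []
    for ctx, choice in zip(contexts, local_choices):
        profiles.append(
            CoverageProfile.from_alignments(
                ctx.rname,
                ctx.start - params.support_window,
                ctx.end + params.support_window,
                choice.values(),
            )
        )
    candidates: dict[str, list[tuple[float, SplitAlignment]]] = defaultdict(list)
    for profile, choice in zip(profiles, local_choices):
        for rid, a in choice.items():
            score = support_score(a, profile, params).value
            candidates[rid].append((score, a))
    final: dict[str, SplitAlignment] = {}
    for rid in sorted(candidates):
        final[rid] = _argmax_support(candidates[rid], params)
    return final
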