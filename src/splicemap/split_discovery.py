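"""Sliding-window discovery of single- and multi-split alignments.

Candidate split alignments (too many mismatches towards one read end) and
candidate multi-split alignments (local placements with both read ends
unaligned) are collected into sliding windows along each reference.  Within
each window the unaligned read part is re-aligned with a small seed against
the (possibly extended) window sequence; each legal placement yields a
two-block split alignment whose split point is chosen to minimise the total
number of substitutions, with ties broken towards canonical splice motifs
(GT..AG / CT..AC) and then the leftmost position.

Multi-split candidates are fragmented into two overlapping sub-reads (the
aligned block plus at most the minimum exon size of flanking sequence); the
fragments' single-split alignments are produced by the same completion
machinery and merged into multi-splits during resolution.

A single run of the window pass serves both candidate kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import RawAlignment, SplitAlignment
from .params import MappingParams
from .resolution import count_block_mismatches, legal_gap, trim_terminal_blocks
from .seed_aligner import completion_boundary


@dataclass(frozen=True)
class Candidate:
    """A window-stage work item: a raw alignment plus its oriented read."""

    raw: RawAlignment
    oriented: str
    kind: str  # 'single' or 'multi'


@dataclass
class SlidingWindow:
    rname: str
    start: int  # ref start of the left-most member
    cap: int    # start + max_window_length: membership boundary
    end: int    # max member end (may exceed cap)
    members: list[Candidate] = field(default_factory=list)


@dataclass(frozen=True)
class Fragment:
    """A contiguous sub-read generated from a candidate multi-split alignment."""

    parent_read_id: str
    sequence: str
    read_offset: int  # position of the fragment start in the (oriented) parent read
    side: str  # 'f1' (left junction) or 'f2' (right junction)


def build_windows(
    candidates: Sequence[Candidate], max_window_length: int
) -> list[SlidingWindow]:
    """Group sorted candidates into per-reference sliding windows.

    A window opens at the left-most unprocessed candidate and admits every
    candidate starting within ``max_window_length``; the next window opens
    at the first member not completely contained within that cap, so every
    candidate belongs to at least one window.
    """
    ordered = sorted(candidates, key=lambda c: (c.raw.rname, c.raw.ref_start, c.raw.strand))
    windows: list[SlidingWindow] = []
    i = 0
    n = len(ordered)
    while i < n:
        first = ordered[i]
        rname = first.raw.rname
        start = first.raw.ref_start
        cap = start + max_window_length
        members = []
        j = i
        while j < n and ordered[j].raw.rname == rname and ordered[j].raw.ref_start < cap:
            members.append(ordered[j])
            j += 1
        end = max(c.raw.ref_end for c in members)
        windows.append(SlidingWindow(rname, start, cap, end, members))
        nxt = None
        for k in range(i + 1, j):
            if ordered[k].raw.ref_end > cap:
                nxt = k
                break
        i = nxt if nxt is not None else j
    return windows


def window_sequence(
    window: SlidingWindow,
    references: dict[str, str],
    x: int,
) -> tuple[str, int]:
    """Reference substring for a window plus any triggered extension.

    The window is extended downstream by ``x`` (the average intron size)
    when a member whose completion lies downstream ends within ``x`` of the
    window end, and upstream symmetrically; extensions are clipped at the
    reference bounds.  Returns (sequence, origin offset of its first base).
    """
    ref = references[window.rname]
    lo, hi = window.start, window.end
    for c in window.members:
        needs_right = c.kind == "multi" or c.raw.seed_anchor == "start"
        needs_left = c.kind == "multi" or c.raw.seed_anchor == "end"
        if needs_right and window.end - c.raw.ref_end < x:
            hi = max(hi, window.end + x)
        if needs_left and c.raw.ref_start - window.start < x:
            lo = min(lo, window.start - x)
    lo = max(lo, 0)
    hi = min(hi, len(ref))
    return ref[lo:hi], lo


def build_window_index(
    reference: str, lo: int, hi: int, seed_len: int
) -> dict[str, list[int]]:
    """Small-seed exact index of reference[lo:hi]; positions are absolute."""
    index: dict[str, list[int]] = {}
    hi = min(hi, len(reference))
    for pos in range(max(lo, 0), hi - seed_len + 1):
        kmer = reference[pos : pos + seed_len]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(pos)
    return index


def _is_canonical(ref: str, donor_end: int, acceptor_start: int) -> bool:
    d = ref[donor_end : donor_end + 2]
    a = ref[acceptor_start - 2 : acceptor_start]
    return (d == "GT" and a == "AG") or (d == "CT" and a == "AC")


def _prefix_mismatches(
    oriented: str, ref: str, diag: int, span_lo: int, span_hi: int
) -> list[int]:
    """Prefix sums of mismatch indicators along one diagonal (out of bounds
    and reference N count as mismatches)."""
    n = span_hi - span_lo
    pre = [0] * (n + 1)
    reflen = len(ref)
    for idx in range(n):
        x = span_lo + idx
        rpos = diag + x
        mm = not (0 <= rpos < reflen) or oriented[x] != ref[rpos] or ref[rpos] == "N"
        pre[idx + 1] = pre[idx] + mm
    return pre


def _best_two_gap_split(
    oriented: str,
    ref: str,
    span_lo: int,
    span_hi: int,
    left_diag: int,
    right_diag: int,
    params: MappingParams,
) -> Optional[tuple[tuple, int]]:
    """Three-block decomposition of a completion span with one indel-sized gap.

    When an indel sits within a seed length of an exon boundary, the exonic
    piece between the junction and the indel is too short to anchor a seed
    and a single-gap split must either absorb the indel as mismatches or
    fuse junction and indel into one false gap.  Here the middle diagonal is
    enumerated at every indel-sized offset from either known diagonal, and
    the two split points are chosen to minimise substitutions.  Returns
    (blocks, substitutions) or None.
    """
    n = span_hi - span_lo
    if n < 3:
        return None
    pre_l = _prefix_mismatches(oriented, ref, left_diag, span_lo, span_hi)
    pre_r = _prefix_mismatches(oriented, ref, right_diag, span_lo, span_hi)
    # candidate middle diagonals: (mid_diag, k1, k2) with k = inserted read bases
    cands: list[tuple[int, int, int]] = []
    for d in range(1, params.max_deletion + 1):
        cands.append((right_diag - d, 0, 0))   # mid | deletion | right
        cands.append((left_diag + d, 0, 0))    # left | deletion | mid
    for i in range(1, params.max_insertion + 1):
        cands.append((right_diag + i, 0, i))   # mid | insertion | right
        cands.append((left_diag - i, i, 0))    # left | insertion | mid
    best: Optional[tuple[int, int, int, int, int, int]] = None
    seen_mid: set[tuple[int, int, int]] = set()
    for mid_diag, k1, k2 in cands:
        if (mid_diag, k1, k2) in seen_mid:
            continue
        seen_mid.add((mid_diag, k1, k2))
        g1 = mid_diag - left_diag + k1   # reference gap left|mid (0 for insertion)
        g2 = right_diag - mid_diag + k2  # reference gap mid|right
        if k1 == 0 and not legal_gap(g1, params):
            continue
        if k2 == 0 and not legal_gap(g2, params):
            continue
        if k1 > 0 and g1 != 0 or k2 > 0 and g2 != 0:
            continue
        a1 = params.min_junction_anchor if (k1 == 0 and g1 >= params.min_intron) else 1
        a2 = params.min_junction_anchor if (k2 == 0 and g2 >= params.min_intron) else 1
        if mid_diag + span_lo < 0 or mid_diag + span_hi > len(ref):
            continue
        pre_m = _prefix_mismatches(oriented, ref, mid_diag, span_lo, span_hi)

        def P(pre, s):  # prefix value at read coordinate s
            return pre[s - span_lo]

        best_head = None  # min over s1 of P(pre_l, s1) - P(pre_m, s1 + k1)
        s1 = span_lo + a1
        total_r = P(pre_r, span_hi)
        for s2 in range(span_lo + a1 + k1 + 1, span_hi - a2 - k2 + 1):
            # admit every s1 with s1 + k1 < s2
            while s1 + k1 < s2:
                head = P(pre_l, s1) - P(pre_m, s1 + k1)
                if best_head is None or head < best_head[0]:
                    best_head = (head, s1)
                s1 += 1
            if best_head is None:
                continue
            cost = best_head[0] + P(pre_m, s2) - P(pre_r, s2 + k2) + (
                total_r
            )
            if best is None or cost < best[0]:
                best = (cost, best_head[1], s2, mid_diag, k1, k2)
    if best is None:
        return None
    cost, s1, s2, mid_diag, k1, k2 = best

    def _P(pre, s):
        return pre[s - span_lo]

    pre_m = _prefix_mismatches(oriented, ref, mid_diag, span_lo, span_hi)
    # junction split points are shift-ambiguous when flanking bases repeat;
    # among equal-cost positions prefer the canonical splice motif
    g1 = mid_diag - left_diag + k1
    if k1 == 0 and g1 >= params.min_intron and not _is_canonical(
        ref, left_diag + s1, mid_diag + s1
    ):
        base = _P(pre_l, s1) - _P(pre_m, s1)
        for cand in range(max(span_lo + 1, s1 - 4), min(s2, s1 + 5)):
            if cand == s1 or _P(pre_l, cand) - _P(pre_m, cand) != base:
                continue
            if _P(pre_m, s2) - _P(pre_m, cand + k1) != 0:
                continue
            if _is_canonical(ref, left_diag + cand, mid_diag + cand):
                s1 = cand
                break
    g2 = right_diag - mid_diag + k2
    if k2 == 0 and g2 >= params.min_intron and not _is_canonical(
        ref, mid_diag + s2, right_diag + s2
    ):
        base = _P(pre_m, s2) - _P(pre_r, s2)
        for cand in range(max(s1 + k1 + 1, s2 - 4), min(span_hi, s2 + 5)):
            if cand == s2 or _P(pre_m, cand) - _P(pre_r, cand) != base:
                continue
            if _P(pre_m, cand) - _P(pre_m, s1 + k1) != 0:
                continue
            if _is_canonical(ref, mid_diag + cand, right_diag + cand):
                s2 = cand
                break
    # overfitting guard: with a free middle diagonal almost any mismatched
    # span can be "improved", so the decomposition is only believable when
    # it is near-perfect, its middle piece matches exactly, and the piece is
    # too short to have been discoverable by seeding in the first place
    if cost > 1:
        return None
    if s2 - (s1 + k1) > 2 * params.window_seed_len:
        return None
    blocks = (
        (left_diag + span_lo, left_diag + s1, span_lo, s1),
        (mid_diag + s1 + k1, mid_diag + s2, s1 + k1, s2),
        (right_diag + s2 + k2, right_diag + span_hi, s2 + k2, span_hi),
    )
    if blocks[0][0] < 0 or blocks[-1][1] > len(ref):
        return None
    mid_pre = _prefix_mismatches(oriented, ref, mid_diag, s1 + k1, s2)
    if mid_pre[-1] != 0:
        return None
    return blocks, cost


def _best_split(
    oriented: str,
    ref: str,
    span_lo: int,
    span_hi: int,
    left_diag: int,
    right_diag: int,
    min_intron: int,
    min_anchor: int = 1,
) -> Optional[tuple[int, int]]:
    """Choose the split point s minimising substitutions for one diagonal pair.

    Returns (s, substitutions) or None when no legal s exists.  Block one is
    oriented[span_lo:s) on ``left_diag``; block two is oriented[s+k:span_hi)
    on ``right_diag`` where k is the number of inserted read bases (0 unless
    the gap is an insertion).  For intron-sized gaps both blocks must keep at
    least ``min_anchor`` read bases; a junction with a shorter anchor cannot
    be verified and such splits are a fertile source of false junctions.
    """
    g = right_diag - left_diag
    kr = -g if g < 0 else 0
    anchor = min_anchor if g >= min_intron else 1
    if left_diag + span_lo < 0 or right_diag + span_hi > len(ref):
        return None
    s_lo = max(span_lo + anchor, -right_diag)
    s_hi = min(span_hi - kr - anchor, len(ref) - left_diag)
    if s_hi < s_lo:
        return None
    # prefix sums of mismatch indicators on both diagonals
    n = span_hi - span_lo
    pre_l = [0] * (n + 1)
    pre_r = [0] * (n + 1)
    for idx in range(n):
        x = span_lo + idx
        lpos = left_diag + x
        rpos = right_diag + x
        lmm = not (0 <= lpos < len(ref)) or oriented[x] != ref[lpos] or ref[lpos] == "N"
        rmm = not (0 <= rpos < len(ref)) or oriented[x] != ref[rpos] or ref[rpos] == "N"
        pre_l[idx + 1] = pre_l[idx] + lmm
        pre_r[idx + 1] = pre_r[idx] + rmm

    def cost(s: int) -> int:
        i = s - span_lo
        j = s + kr - span_lo
        return pre_l[i] + (pre_r[n] - pre_r[j])

    best_cost = None
    candidates: list[int] = []
    for s in range(s_lo, s_hi + 1):
        c = cost(s)
        if best_cost is None or c < best_cost:
            best_cost = c
            candidates = [s]
        elif c == best_cost:
            candidates.append(s)
    if best_cost is None:
        return None
    if len(candidates) > 1 and g >= min_intron:
        canonical = [
            s
            for s in candidates
            if _is_canonical(ref, left_diag + s, right_diag + s)
        ]
        if canonical:
            candidates = canonical
    return candidates[0], best_cost


def _completions(
    read_id: str,
    oriented: str,
    rname: str,
    strand: str,
    ref: str,
    span_lo: int,
    span_hi: int,
    known_diag: int,
    u_lo: int,
    u_hi: int,
    side: str,
    window_index: dict[str, list[int]],
    params: MappingParams,
    source: str,
    fragment_side: Optional[str] = None,
) -> list[SplitAlignment]:
    """Shared completion engine for candidate splits and fragments.

    The read part oriented[u_lo:u_hi) is unexplained; every small-seed hit of
    it inside the window proposes an alternative diagonal, and each legal
    diagonal pair yields one two-block split alignment.
    """
    ks = params.window_seed_len
    u = oriented[u_lo:u_hi]
    if len(u) < ks:
        return []
    step = max(1, ks // 2)
    offsets = list(range(0, len(u) - ks + 1, step))
    if offsets[-1] != len(u) - ks:
        offsets.append(len(u) - ks)
    diagonals: set[int] = set()
    for off in offsets:
        for q in window_index.get(u[off : off + ks], ()):
            diagonals.add(q - (u_lo + off))
    out: list[SplitAlignment] = []
    for diag2 in sorted(diagonals):
        if diag2 == known_diag:
            continue
        if side == "right":
            left_diag, right_diag = known_diag, diag2
        else:
            left_diag, right_diag = diag2, known_diag
        g = right_diag - left_diag
        if not legal_gap(g, params):
            continue
        found = _best_split(
            oriented,
            ref,
            span_lo,
            span_hi,
            left_diag,
            right_diag,
            params.min_intron,
            params.min_junction_anchor,
        )
        if found is None or found[1] >= 3:
            # a poor single-gap optimum can mean the span crosses a junction
            # AND a nearby indel; look for a three-block decomposition
            two_gap = _best_two_gap_split(
                oriented, ref, span_lo, span_hi, left_diag, right_diag, params
            )
            if two_gap is not None and (found is None or found[1] - two_gap[1] >= 3):
                blocks3, subs3 = two_gap
                try:
                    out.append(
                        SplitAlignment(
                            read_id=read_id,
                            rname=rname,
                            strand=strand,
                            blocks=blocks3,
                            mismatch_count=subs3,
                            read_length=len(oriented),
                            source=source,
                            fragment_side=fragment_side,
                        )
                    )
                except ValueError:
                    pass
        if found is None:
            continue
        s, subs = found
        kr = -g if g < 0 else 0
        blocks = (
            (left_diag + span_lo, left_diag + s, span_lo, s),
            (right_diag + s + kr, right_diag + span_hi, s + kr, span_hi),
        )
        if subs > params.max_mismatches:
            # an indel-sized span may cross a second gap (e.g. an exon's
            # deletion plus the next junction): keep the within-budget part
            # clipped so resolution can re-split the remainder across a
            # known site later.  Junction-sized completions are not trimmed:
            # a clipped stump of a chance diagonal would mint a false site.
            if g >= params.min_intron:
                continue
            blocks = trim_terminal_blocks(
                oriented, ref, blocks, params.max_mismatches, 1, side == "right"
            )
            if blocks is None:
                continue
            subs = count_block_mismatches(oriented, ref, blocks)
            if subs > params.max_mismatches:
                continue
        try:
            aln = SplitAlignment(
                read_id=read_id,
                rname=rname,
                strand=strand,
                blocks=blocks,
                mismatch_count=subs,
                read_length=len(oriented),
                source=source,
                fragment_side=fragment_side,
            )
        except ValueError:
            continue
        out.append(aln)
    return out


def complete_single_split(
    candidate: Candidate,
    ref: str,
    window_index: dict[str, list[int]],
    params: MappingParams,
) -> list[SplitAlignment]:
    """Complete a candidate single-split alignment within its window.

    The unaligned read part (beyond the last allowed mismatch) is re-aligned
    with the small window seed; each completing placement with a legal gap
    size and at most the allowed mismatches yields one split alignment.
    """
    raw = candidate.raw
    u_lo, u_hi = completion_boundary(raw, params.max_mismatches)
    side = "right" if raw.seed_anchor == "start" else "left"
    diag = raw.ref_start - raw.read_start
    return _completions(
        read_id=raw.read_id,
        oriented=candidate.oriented,
        rname=raw.rname,
        strand=raw.strand,
        ref=ref,
        span_lo=0,
        span_hi=raw.read_length,
        known_diag=diag,
        u_lo=u_lo,
        u_hi=u_hi,
        side=side,
        window_index=window_index,
        params=params,
        source="initial",
    )


def make_fragments(local: RawAlignment, oriented: str, e: int) -> tuple[Fragment, Fragment]:
    """Generate the two fragments of a candidate multi-split alignment.

    With the read aligned at oriented[i:j), the first fragment carries at
    most ``e`` bases of the unaligned prefix plus the aligned block; the
    second the aligned block plus at most ``e`` bases of the unaligned
    suffix.  Short prefixes/suffixes are truncated at the read bounds.
    """
    i0, j0 = local.read_start, local.read_end
    l = local.read_length
    if i0 == 0 and j0 == l:
        raise ValueError("alignment covers the whole read; not a multi-split candidate")
    f1_lo = max(0, i0 - e)
    f2_hi = min(l, j0 + e)
    f1 = Fragment(local.read_id, oriented[f1_lo:j0], f1_lo, "f1")
    f2 = Fragment(local.read_id, oriented[i0:f2_hi], i0, "f2")
    return f1, f2


def fragment_single_splits(
    candidate: Candidate,
    ref: str,
    window_index: dict[str, list[int]],
    params: MappingParams,
) -> list[SplitAlignment]:
    """Single-split alignments for the two fragments of a multi-split candidate.

    Results are expressed directly in parent-read coordinates (via the
    fragment offsets) and tagged with their side so resolution can merge
    them; duplicates are removed.
    """
    raw = candidate.raw
    oriented = candidate.oriented
    f1, f2 = make_fragments(raw, oriented, params.min_exon)
    diag = raw.ref_start - raw.read_start
    i0, j0 = raw.read_start, raw.read_end
    out: list[SplitAlignment] = []
    # f1: unaligned prefix, aligned tail -> left junction
    out += _completions(
        raw.read_id,
        oriented,
        raw.rname,
        raw.strand,
        ref,
        span_lo=f1.read_offset,
        span_hi=j0,
        known_diag=diag,
        u_lo=f1.read_offset,
        u_hi=i0,
        side="left",
        window_index=window_index,
        params=params,
        source="fragment",
        fragment_side="f1",
    )
    # f2: aligned head, unaligned suffix -> right junction
    f2_hi = f2.read_offset + len(f2.sequence)
    out += _completions(
        raw.read_id,
        oriented,
        raw.rname,
        raw.strand,
        ref,
        span_lo=i0,
        span_hi=f2_hi,
        known_diag=diag,
        u_lo=j0,
        u_hi=f2_hi,
        side="right",
        window_index=window_index,
        params=params,
        source="fragment",
        fragment_side="f2",
    )
    seen = set()
    dedup = []
    for a in out:
        key = a.junction_key() + (a.fragment_side,)
        if key not in seen:
            seen.add(key)
            dedup.append(a)
    return dedup
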