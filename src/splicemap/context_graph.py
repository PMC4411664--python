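"""Context clustering and within-context alignment extension.

A context is a cluster of read alignments on one reference whose neighbours
lie within ``d_min`` of each other, capped at a maximum genomic span
``d_max``; it approximates the footprint of one gene or a group of
overlapping genes.  Contexts are processed independently: within each one,
full and partial alignments are re-split across splice sites discovered from
other reads, and reads that already carry a split alignment have all
compatible split variants enumerated, so that the best-supported alternative
can be selected during resolution.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from .model import Context, SplitAlignment, SpliceSite
from .params import MappingParams
from .resolution import count_block_mismatches, legal_gap, trim_terminal_blocks


def build_contexts(
    alignments: Iterable[SplitAlignment], d_min: int, d_max: int
) -> list[Context]:
    """Single-linkage clustering of alignments into contexts, per reference.

    Sorted by start, an alignment opens a new context when its distance to
    the previous member's end reaches ``d_min`` or when admitting it would
    push the context span beyond ``d_max`` (a single alignment may exceed
    ``d_max`` on its own).  A read may appear in several contexts through
    different alignments.
    """
    by_ref: dict[str, list[SplitAlignment]] = defaultdict(list)
    for a in alignments:
        by_ref[a.rname].append(a)
    contexts: list[Context] = []
    cid = 0
    for rname in sorted(by_ref):
        members = sorted(by_ref[rname], key=lambda a: (a.ref_start, a.ref_end, a.read_id))
        cur: Optional[Context] = None
        cur_max_end = 0
        for a in members:
            if (
                cur is None
                or a.ref_start - cur_max_end >= d_min
                or (max(a.ref_end, cur_max_end) - cur.start > d_max and a.ref_start > cur.start)
            ):
                cur = Context(id=cid, rname=rname, start=a.ref_start, end=a.ref_end)
                cid += 1
                contexts.append(cur)
                cur_max_end = a.ref_end
            cur.members.append(a)
            cur_max_end = max(cur_max_end, a.ref_end)
            cur.end = cur_max_end
        # done per reference
    return contexts


def context_sites(context: Context) -> list[SpliceSite]:
    """Distinct splice sites present in the context's split alignments."""
    sites = set()
    for a in context.members:
        for donor_end, acceptor_start, read_gap in a.gaps():
            sites.add(SpliceSite(a.rname, donor_end, acceptor_start, max(read_gap, 0)))
    return sorted(sites, key=lambda s: (s.donor_end, s.acceptor_start, s.read_gap))


def trusted_sites(context: Context) -> set[SpliceSite]:
    """Sites solid enough to re-split other reads across with minimal anchors.

    A site is trusted when at least two distinct reads use it or when one
    read uses it without any mismatch; a site seen once, with mismatches,
    may well be a chance completion of a noisy read and only supports
    re-splits that leave a verifiable anchor on both sides.
    """
    readers: dict[SpliceSite, set[str]] = defaultdict(set)
    min_subs: dict[SpliceSite, int] = {}
    for a in context.members:
        for donor_end, acceptor_start, read_gap in a.gaps():
            site = SpliceSite(a.rname, donor_end, acceptor_start, max(read_gap, 0))
            readers[site].add(a.read_id)
            if site not in min_subs or a.mismatch_count < min_subs[site]:
                min_subs[site] = a.mismatch_count
    return {
        s for s, rs in readers.items() if len(rs) >= 2 or min_subs[s] == 0
    }


def _internal_blocks_ok(blocks, min_exon: int, min_intron: int) -> bool:
    """Internal blocks flanked by introns on both sides are internal exons
    and must be at least ``min_exon`` long; a block bounded by an indel gap
    is just a piece of one exon and only needs to be non-empty."""
    for i in range(1, len(blocks) - 1):
        left_gap = blocks[i][0] - blocks[i - 1][1]
        right_gap = blocks[i + 1][0] - blocks[i][1]
        if (
            left_gap >= min_intron
            and right_gap >= min_intron
            and blocks[i][1] - blocks[i][0] < min_exon
        ):
            return False
    return True


def resplit_terminal(
    a: SplitAlignment,
    site: SpliceSite,
    oriented: str,
    ref: str,
    params: MappingParams,
    trusted: bool = True,
) -> list[SplitAlignment]:
    """Re-split a terminal block of an alignment across a known splice site.

    If the site's donor lies inside the last block, the read tail beyond the
    donor (including soft-clipped bases) is moved to the acceptor side; if
    the acceptor lies inside the first block, the read head is moved before
    the donor.  For indel sites both moves can apply to the same block and
    both are attempted.  Variants are kept only when their substitutions stay
    within the mismatch budget - a moved piece that itself crosses another
    gap is kept trimmed so a later pass can re-split the remainder - and all
    internal blocks respect the minimum exon size.
    """
    if site.rname != a.rname or not legal_gap(site.gap_size, params):
        return []
    k = site.read_gap
    # re-splits across untrusted junctions need a verifiable anchor on both
    # sides; trusted sites and indel gaps accept single-base anchors
    anchor = 1
    if not trusted and site.gap_size >= params.min_intron:
        anchor = params.min_junction_anchor
    proposals: list[tuple[tuple, bool]] = []
    last = a.blocks[-1]
    first = a.blocks[0]
    if last[0] < site.donor_end < last[1]:
        # move the read tail (including any soft-clipped bases) to the acceptor
        t = last[2] + (site.donor_end - last[0])
        tail_len = a.read_length - t - k
        if tail_len >= anchor and t - last[2] >= anchor:
            end = site.acceptor_start + tail_len
            proposals.append(
                (
                    a.blocks[:-1]
                    + (
                        (last[0], site.donor_end, last[2], t),
                        (site.acceptor_start, end, t + k, a.read_length),
                    ),
                    True,
                )
            )
    if first[0] < site.acceptor_start < first[1]:
        # move the read head (including any soft-clipped bases) before the donor
        t = first[2] + (site.acceptor_start - first[0])
        head_len = t - k
        if head_len >= anchor and first[3] - t >= anchor:
            proposals.append(
                (
                    (
                        (site.donor_end - head_len, site.donor_end, 0, t - k),
                        (site.acceptor_start, first[1], t, first[3]),
                    )
                    + a.blocks[1:],
                    False,
                )
            )
    # substitute an alternative acceptor (or donor) into an existing gap that
    # shares the other coordinate: the flanking blocks shift along
    for i, (donor_end, acceptor_start, read_gap) in enumerate(a.gaps()):
        if max(read_gap, 0) != k:
            continue
        if donor_end == site.donor_end and acceptor_start != site.acceptor_start:
            delta = site.acceptor_start - acceptor_start
            shifted = tuple(
                (rs + delta, re_ + delta, qs, qe) for rs, re_, qs, qe in a.blocks[i + 1 :]
            )
            proposals.append((a.blocks[: i + 1] + shifted, True))
        elif acceptor_start == site.acceptor_start and donor_end != site.donor_end:
            delta = site.donor_end - donor_end
            shifted = tuple(
                (rs + delta, re_ + delta, qs, qe) for rs, re_, qs, qe in a.blocks[: i + 1]
            )
            proposals.append((shifted + a.blocks[i + 1 :], False))
    out: list[SplitAlignment] = []
    for new_blocks, moved_last in proposals:
        if new_blocks[0][0] < 0 or new_blocks[-1][1] > len(ref):
            continue
        if not _internal_blocks_ok(new_blocks, params.min_exon, params.min_intron):
            continue
        try:
            subs = count_block_mismatches(oriented, ref, new_blocks)
            if subs > params.max_mismatches:
                new_blocks = trim_terminal_blocks(
                    oriented, ref, new_blocks, params.max_mismatches, anchor, moved_last
                )
                if new_blocks is None:
                    continue
                subs = count_block_mismatches(oriented, ref, new_blocks)
                if subs > params.max_mismatches:
                    continue
            out.append(
                SplitAlignment(
                    read_id=a.read_id,
                    rname=a.rname,
                    strand=a.strand,
                    blocks=new_blocks,
                    mismatch_count=subs,
                    read_length=a.read_length,
                    source="extension",
                    fragment_side=a.fragment_side,
                )
            )
        except ValueError:
            continue
    return out


def extend_to_read_ends(
    a: SplitAlignment, oriented: str, ref: str, params: MappingParams
) -> Optional[SplitAlignment]:
    """Extend a clipped alignment's terminal blocks out to the read ends.

    Each side is extended greedily, one base at a time, as far as the total
    substitution count allows (clipped at the reference bounds), so a read
    whose tail crosses a further junction is extended up to the point where
    the mismatch budget runs out and can be re-split there later.  Returns
    None when nothing changes.
    """
    first = a.blocks[0]
    last = a.blocks[-1]
    budget = params.max_mismatches - a.mismatch_count
    if budget < 0:
        return None
    # left extension
    left_gain = 0
    subs_left = 0
    while left_gain < min(first[2], first[0]):
        q = first[2] - left_gain - 1
        r = first[0] - left_gain - 1
        miss = oriented[q] != ref[r] or ref[r] == "N"
        if subs_left + miss > budget:
            break
        subs_left += miss
        left_gain += 1
    budget -= subs_left
    # right extension
    right_gain = 0
    subs_right = 0
    max_right = min(a.read_length - last[3], len(ref) - last[1])
    while right_gain < max_right:
        q = last[3] + right_gain
        r = last[1] + right_gain
        miss = oriented[q] != ref[r] or ref[r] == "N"
        if subs_right + miss > budget:
            break
        subs_right += miss
        right_gain += 1
    if left_gain == 0 and right_gain == 0:
        return None
    new_first = (first[0] - left_gain, first[1], first[2] - left_gain, first[3])
    new_last = (last[0], last[1] + right_gain, last[2], last[3] + right_gain)
    if len(a.blocks) == 1:
        new_first = (
            first[0] - left_gain,
            first[1] + right_gain,
            first[2] - left_gain,
            first[3] + right_gain,
        )
        blocks = (new_first,)
    else:
        blocks = (new_first,) + a.blocks[1:-1] + (new_last,)
    subs = count_block_mismatches(oriented, ref, blocks)
    if subs > params.max_mismatches:
        return None
    return SplitAlignment(
        read_id=a.read_id,
        rname=a.rname,
        strand=a.strand,
        blocks=blocks,
        mismatch_count=subs,
        read_length=a.read_length,
        source="extension",
        fragment_side=a.fragment_side,
    )


def extend_with_known_junctions(
    context: Context,
    oriented_reads: dict[tuple[str, str], str],
    references: dict[str, str],
    params: MappingParams,
) -> Context:
    """Create additional split alignments across the context's known junctions.

    Full and partial (single-block) alignments overlapping a splice site of
    another read are re-split across it; originals are retained as
    alternatives, and nothing exceeding the mismatch budget is added.
    """
    sites = context_sites(context)
    if not sites:
        return context
    trust = trusted_sites(context)
    ref = references[context.rname]
    added: list[SplitAlignment] = []
    seen = {a.junction_key() for a in context.members}
    for a in context.members:
        if len(a.blocks) != 1:
            continue
        oriented = oriented_reads[(a.read_id, a.strand)]
        for site in sites:
            for v in resplit_terminal(a, site, oriented, ref, params, site in trust):
                if v.junction_key() not in seen:
                    seen.add(v.junction_key())
                    added.append(v)
    context.members.extend(added)
    return context


def enumerate_split_variants(
    read_id: str,
    context: Context,
    oriented_reads: dict[tuple[str, str], str],
    references: dict[str, str],
    params: MappingParams,
    sites: Optional[list[SpliceSite]] = None,
    trust: Optional[set[SpliceSite]] = None,
) -> list[SplitAlignment]:
    """All split variants of one read compatible with the context's junctions.

    Starting from the read's existing split alignments, terminal blocks are
    iteratively re-split across additional context junctions (breadth-first,
    de-duplicated, capped); this also produces multi-split variants when a
    single-split alignment overlaps a further junction.
    """
    if sites is None:
        sites = context_sites(context)
    base = [a for a in context.members if a.read_id == read_id and len(a.blocks) > 1]
    if not base or not sites:
        return []
    if trust is None:
        trust = trusted_sites(context)
    ref = references[context.rname]
    seen = {a.junction_key() for a in context.members if a.read_id == read_id}
    queue = list(base)
    new_variants: list[SplitAlignment] = []
    budget = params.variant_cap * 8  # hard stop on pathological contexts
    while queue and budget > 0:
        a = queue.pop(0)
        oriented = oriented_reads[(a.read_id, a.strand)]
        for site in sites:
            budget -= 1
            for v in resplit_terminal(a, site, oriented, ref, params, site in trust):
                if v.junction_key() not in seen:
                    seen.add(v.junction_key())
                    new_variants.append(v)
                    queue.append(v)
            if budget <= 0:
                break
    new_variants.sort(
        key=lambda a: (a.effective_mismatches, len(a.blocks), a.ref_start, a.blocks)
    )
    return new_variants[: params.variant_cap]
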