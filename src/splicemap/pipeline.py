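"""End-to-end mapping pipeline.

Five stages: (1) seeded initial alignment and four-way classification,
including sliding-window completion of candidate single-split alignments and
fragmentation of candidate multi-split alignments; (2) context clustering;
(3) within-context alignment extension across known junctions; (4) local
resolution (evidence-scored site selection, fragment merging, support-score
argmax per read); (5) global resolution across contexts and SAM output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import context_graph, resolution, split_discovery
from .io_formats import cigar_from_split
from .model import (
    AlignmentCategory,
    Read,
    ReferenceSequence,
    SamRecord,
    SplitAlignment,
    revcomp,
)
from .params import DEFAULT_PARAMS, MappingParams
from .seed_aligner import BuiltinAligner, classify

logger = logging.getLogger(__name__)


@dataclass
class MappingResult:
    records: list[SamRecord]
    references: list[ReferenceSequence]
    stats: dict = field(default_factory=dict)


def _raw_to_alignment(raw, source: str) -> SplitAlignment:
    return SplitAlignment(
        read_id=raw.read_id,
        rname=raw.rname,
        strand=raw.strand,
        blocks=((raw.ref_start, raw.ref_end, raw.read_start, raw.read_end),),
        mismatch_count=len(raw.mismatches),
        read_length=raw.read_length,
        source=source,
    )


def _trim_partial(raw, params: MappingParams) -> Optional[SplitAlignment]:
    """Clip a too-mismatched raw alignment down to its well-aligned part.

    The aligned side keeps everything up to (not including) the first
    mismatch beyond the budget, then sheds terminal mismatches so the block
    ends on matching bases.
    """
    m = params.max_mismatches
    mism = set(raw.mismatches)
    eff = raw.effective_mismatch_positions()
    diag = raw.ref_start - raw.read_start
    if raw.seed_anchor == "start":
        hi = eff[m] if len(eff) > m else raw.read_end
        qs, qe = raw.read_start, min(hi, raw.read_end)
        while qe > qs and (qe - 1) in mism:
            qe -= 1
    else:
        lo = (eff[-(m + 1)] + 1) if len(eff) > m else raw.read_start
        qs, qe = max(lo, raw.read_start), raw.read_end
        while qs < qe and qs in mism:
            qs += 1
    if qe - qs < params.window_seed_len:
        return None
    subs = sum(1 for p in raw.mismatches if qs <= p < qe)
    if subs > params.max_mismatches:
        return None
    return SplitAlignment(
        read_id=raw.read_id,
        rname=raw.rname,
        strand=raw.strand,
        blocks=((diag + qs, diag + qe, qs, qe),),
        mismatch_count=subs,
        read_length=raw.read_length,
        source="partial",
    )


class _VariantPool:
    """Per-read alignment variants, de-duplicated by placement."""

    def __init__(self):
        self.by_read: dict[str, list[SplitAlignment]] = {}
        self._seen: set = set()

    def add(self, a: Optional[SplitAlignment]) -> bool:
        if a is None:
            return False
        key = a.junction_key() + (a.fragment_side,)
        if key in self._seen:
            return False
        self._seen.add(key)
        self.by_read.setdefault(a.read_id, []).append(a)
        return True

    def all_variants(self) -> list[SplitAlignment]:
        return [a for vs in self.by_read.values() for a in vs]


def map_reads(
    references: Sequence[ReferenceSequence],
    reads: Iterable[Read],
    params: MappingParams = DEFAULT_PARAMS,
    annotation: Optional[set[tuple[str, int, int]]] = None,
    aligner=None,
) -> MappingResult:
    """Map single-end reads against one or more references; emit SAM records.

    Records are returned in input read order; reads without a surviving
    alignment get an unmapped record (flag 4).  The run is deterministic:
    identical inputs produce byte-identical output.
    """
    params.validate()
    aligner = aligner or BuiltinAligner()
    refs = {r.name: r.sequence for r in references}
    index = aligner.build_index(references, params.seed_len)
    local_index = None
    pool = _VariantPool()
    candidates: list[split_discovery.Candidate] = []
    order: list[Read] = []
    oriented_cache: dict[tuple[str, str], str] = {}
    n_rejected = 0

    def oriented_of(read: Read, strand: str) -> str:
        key = (read.id, strand)
        if key not in oriented_cache:
            oriented_cache[key] = read.sequence if strand == "+" else revcomp(read.sequence)
        return oriented_cache[key]

    # ---- stage 1: initial alignments -------------------------------------
    for read in reads:
        order.append(read)
        if len(read) < 2 * params.seed_len:
            logger.warning(
                "read %s shorter than twice the seed length; rejected", read.id
            )
            n_rejected += 1
            continue
        raws = aligner.align_anchored(
            read, index, params.max_mismatches, params.max_hits, "start"
        )
        if not raws:
            raws = aligner.align_anchored(
                read, index, params.max_mismatches, params.max_hits, "end"
            )
        full_found = False
        for raw in raws:
            cat = classify(raw, params.max_mismatches, params.mismatch_end_dist)
            ori = oriented_of(read, raw.strand)
            if cat is AlignmentCategory.FULL:
                full_found = True
                pool.add(_raw_to_alignment(raw, "full"))
            elif cat is AlignmentCategory.CANDIDATE_SINGLE_SPLIT:
                candidates.append(split_discovery.Candidate(raw, ori, "single"))
                pool.add(_trim_partial(raw, params))
            elif cat is AlignmentCategory.PARTIAL:
                pool.add(_trim_partial(raw, params))
        if not full_found:
            if local_index is None:
                local_index = aligner.build_index(references, params.local_seed_len)
            locals_ = aligner.align_local(
                read,
                local_index,
                min_aligned=params.local_seed_len,
                flank_mismatches=params.local_flank_mismatches,
                max_hits=params.max_hits,
            )
            for raw in locals_:
                cat = classify(raw, params.max_mismatches, params.mismatch_end_dist)
                ori = oriented_of(read, raw.strand)
                if cat is AlignmentCategory.CANDIDATE_MULTI_SPLIT:
                    candidates.append(split_discovery.Candidate(raw, ori, "multi"))
                    pool.add(_raw_to_alignment(raw, "local"))
                elif cat is AlignmentCategory.FULL:
                    pool.add(_raw_to_alignment(raw, "local"))
                elif cat is AlignmentCategory.CANDIDATE_SINGLE_SPLIT:
                    candidates.append(split_discovery.Candidate(raw, ori, "single"))
                    pool.add(_trim_partial(raw, params))
                else:
                    pool.add(_trim_partial(raw, params))

    # ---- sliding-window completion ---------------------------------------
    windows = split_discovery.build_windows(candidates, params.max_window)
    n_completions = 0
    for window in windows:
        ref = refs[window.rname]
        seq, origin = split_discovery.window_sequence(window, refs, params.avg_intron)
        win_index = split_discovery.build_window_index(
            ref, origin, origin + len(seq), params.window_seed_len
        )
        for cand in window.members:
            if cand.kind == "single":
                alns = split_discovery.complete_single_split(cand, ref, win_index, params)
            else:
                alns = split_discovery.fragment_single_splits(cand, ref, win_index, params)
            for a in alns:
                n_completions += pool.add(a)
    logger.info(
        "windows: %d, completions: %d, candidates: %d",
        len(windows),
        n_completions,
        len(candidates),
    )

    # ---- contexts, extension, resolution ---------------------------------
    contexts = context_graph.build_contexts(
        pool.all_variants(), params.d_min, params.d_max
    )
    local_choices = []
    for ctx in contexts:
        seen = {a.junction_key() + (a.fragment_side,) for a in ctx.members}

        def _extend_clipped(members):
            added = []
            for a in members:
                if a.n_clipped == 0:
                    continue
                v = context_graph.extend_to_read_ends(
                    a, oriented_cache[(a.read_id, a.strand)], refs[ctx.rname], params
                )
                if v is not None:
                    key = v.junction_key() + (v.fragment_side,)
                    if key not in seen:
                        seen.add(key)
                        added.append(v)
            return added

        # Two rounds: extending a clipped alignment can push it across a
        # junction discovered by other reads, after which it can be re-split;
        # the re-split tail is clipped again and needs one more extension.
        for _round in range(2):
            ctx.members.extend(_extend_clipped(ctx.members))
            context_graph.extend_with_known_junctions(ctx, oriented_cache, refs, params)
            seen.update(a.junction_key() + (a.fragment_side,) for a in ctx.members)
            split_reads = sorted({a.read_id for a in ctx.members if len(a.blocks) > 1})
            ctx_sites = context_graph.context_sites(ctx)
            ctx_trust = context_graph.trusted_sites(ctx)
            for rid in split_reads:
                new_vs = context_graph.enumerate_split_variants(
                    rid, ctx, oriented_cache, refs, params, ctx_sites, ctx_trust
                )
                for v in new_vs:
                    key = v.junction_key() + (v.fragment_side,)
                    if key not in seen:
                        seen.add(key)
                        ctx.members.append(v)
        ctx.members.extend(_extend_clipped(ctx.members))
        # evidence-scored site selection
        counts = resolution.collect_sites(ctx.members, params.max_mismatches)
        retained = resolution.select_best_sites(
            counts, params.evidence_w, annotation, params.annotation_bonus
        )
        ctx.members = [
            a
            for a in ctx.members
            if len(a.blocks) == 1 or resolution.uses_only_sites(a, retained)
        ]
        # merge fragment single-splits into multi-splits
        merged_new = _merge_fragments(ctx, oriented_cache, refs, params, seen)
        ctx.members.extend(merged_new)
        if merged_new:
            # a merged multi-split can still cross a surviving indel site or
            # junction near the read ends; one more re-split + extension pass
            for rid in sorted({a.read_id for a in merged_new}):
                for v in context_graph.enumerate_split_variants(
                    rid, ctx, oriented_cache, refs, params
                ):
                    key = v.junction_key() + (v.fragment_side,)
                    if key not in seen:
                        seen.add(key)
                        ctx.members.append(v)
            ctx.members.extend(_extend_clipped(ctx.members))
        local_choices.append(resolution.resolve_local(ctx, params))
    final = resolution.resolve_global(contexts, local_choices, params)

    # ---- SAM output --------------------------------------------------------
    records = []
    n_mapped = 0
    for read in order:
        a = final.get(read.id)
        if a is None:
            records.append(
                SamRecord(
                    qname=read.id,
                    flag=4,
                    rname="*",
                    pos=-1,
                    mapq=0,
                    cigar="*",
                    seq=read.sequence,
                    qual=read.qualities or "*",
                )
            )
            continue
        n_mapped += 1
        gap_types = [
            resolution.classify_gap(
                g,
                params.max_insertion,
                params.max_deletion,
                params.min_intron,
                params.max_intron,
            )
            for g in a.gap_sizes()
        ]
        cigar = cigar_from_split(a, len(read), gap_types)
        seq = read.sequence if a.strand == "+" else revcomp(read.sequence)
        qual = read.qualities or "*"
        if a.strand == "-" and qual != "*":
            qual = qual[::-1]
        records.append(
            SamRecord(
                qname=read.id,
                flag=0 if a.strand == "+" else 16,
                rname=a.rname,
                pos=a.ref_start,
                mapq=255,
                cigar=cigar,
                seq=seq,
                qual=qual,
                tags=(f"NM:i:{a.mismatch_count}", f"XC:Z:{a.source}"),
            )
        )
    stats = {
        "reads": len(order),
        "mapped": n_mapped,
        "unmapped": len(order) - n_mapped,
        "rejected_short": n_rejected,
        "windows": len(windows),
        "contexts": len(contexts),
        "completions": n_completions,
    }
    logger.info("mapped %d/%d reads", n_mapped, len(order))
    return MappingResult(records=records, references=list(references), stats=stats)


def _merge_fragments(ctx, oriented_cache, refs, params, seen) -> list[SplitAlignment]:
    """Merge surviving f1/f2 fragment splits per read into multi-splits."""
    by_side: dict[str, dict[str, list[SplitAlignment]]] = {}
    for a in ctx.members:
        if a.fragment_side and len(a.blocks) >= 2:
            by_side.setdefault(a.read_id, {}).setdefault(a.fragment_side, []).append(a)
    out: list[SplitAlignment] = []
    for rid in sorted(by_side):
        sides = by_side[rid]
        f1s = sorted(sides.get("f1", ()), key=resolution._tie_key)[:6]
        f2s = sorted(sides.get("f2", ()), key=resolution._tie_key)[:6]
        for f1 in f1s:
            for f2 in f2s:
                merged = resolution.merge_fragment_splits(
                    f1, f2, oriented_cache[(rid, f1.strand)], refs[ctx.rname], params
                )
                if merged is None:
                    continue
                for cand in (
                    merged,
                    context_graph.extend_to_read_ends(
                        merged, oriented_cache[(rid, merged.strand)], refs[ctx.rname], params
                    ),
                ):
                    if cand is None:
                        continue
                    key = cand.junction_key() + (cand.fragment_side,)
                    if key not in seen:
                        seen.add(key)
                        out.append(cand)
    return out
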