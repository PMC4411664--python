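"""Mapper evaluation against simulator ground truth.

Metrics:

* splice recall and FDR, where a splice is one junction occurrence in one
  particular read and a match requires exact donor and acceptor coordinates;
* base-level read categories (perfect / part correct / no base correct /
  unmapped), reported separately for spliced and unspliced reads;
* per-junction-count tallies with precision, recall and F-measure for reads
  spanning k = 0..3 junctions (indel gaps are ignored when counting
  junctions);
* indel precision/recall/F stratified by type and size 1-10 (undefined when
  nothing of that size was predicted).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import iter_cigar
from .model import SamRecord, TruthRecord

DEFAULT_MIN_INTRON = 50


# ---------------------------------------------------------------------------
# Base-level maps (FASTQ read position -> reference position or None)
# ---------------------------------------------------------------------------

def truth_base_map(rec: TruthRecord, read_length: int) -> list[Optional[int]]:
    """Reference position of every FASTQ read base according to the truth.

    Inserted bases map to None.  Truth coordinates are stored in oriented
    (transcript-walk) order; the map is flipped for '-' reads so it is keyed
    by FASTQ position.
    """
    ins_at: dict[int, int] = {ev.read_pos: ev.length for ev in rec.indels if ev.kind == "I"}
    oriented: list[Optional[int]] = []
    block_iter = iter(rec.blocks)
    cur = next(block_iter)
    ref = cur[0]
    p = 0
    while p < read_length:
        k = ins_at.get(p)
        if k:
            oriented.extend([None] * k)
            p += k
            continue
        while ref >= cur[1]:
            cur = next(block_iter)
            ref = cur[0]
        oriented.append(ref)
        ref += 1
        p += 1
    if rec.strand == "-":
        oriented.reverse()
    return oriented


def predicted_base_map(rec: SamRecord) -> list[Optional[int]]:
    """Reference position of every FASTQ read base in a SAM record.

    Soft-clipped and inserted bases map to None; the map is keyed by FASTQ
    position (flipped for reverse-strand records).
    """
    oriented: list[Optional[int]] = []
    ref = rec.pos
    for n, op in iter_cigar(rec.cigar):
        if op in "M=X":
            oriented.extend(range(ref, ref + n))
            ref += n
        elif op in "IS":
            oriented.extend([None] * n)
        elif op in "DN":
            ref += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    if rec.is_reverse:
        oriented.reverse()
    return oriented


def predicted_junctions(rec: SamRecord) -> list[tuple[int, int]]:
    """Intron intervals (N gaps) of a mapped SAM record."""
    out = []
    ref = rec.pos
    for n, op in iter_cigar(rec.cigar):
        if op in "M=XD":
            ref += n
        elif op == "N":
            out.append((ref, ref + n))
            ref += n
    return out


def predicted_indels(rec: SamRecord) -> list[tuple[str, int, int]]:
    """(kind, ref position, length) of every I/D operation in a SAM record."""
    out = []
    ref = rec.pos
    for n, op in iter_cigar(rec.cigar):
        if op in "M=X":
            ref += n
        elif op == "D":
            out.append(("D", ref, n))
            ref += n
        elif op == "N":
            ref += n
        elif op == "I":
            out.append(("I", ref, n))
    return out


def _pair_records(
    records: Iterable[SamRecord], truths: Sequence[TruthRecord]
) -> tuple[dict[str, TruthRecord], dict[str, SamRecord]]:
    truth_by_id = {t.read_id: t for t in truths}
    rec_by_id: dict[str, SamRecord] = {}
    unknown = []
    for r in records:
        if r.qname not in truth_by_id:
            unknown.append(r.qname)
        if r.qname in rec_by_id:
            raise ValueError(f"duplicate SAM record for read {r.qname!r}")
        rec_by_id[r.qname] = r
    if unknown:
        raise ValueError(f"predictions for unknown reads: {sorted(unknown)[:10]}")
    return truth_by_id, rec_by_id


# ---------------------------------------------------------------------------
# Splice recall / FDR
# ---------------------------------------------------------------------------

@dataclass
class SpliceConfusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def recall(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 0.0

    @property
    def fdr(self) -> float:
        predicted = self.tp + self.fp
        return self.fp / predicted if predicted else 0.0


def splice_confusion(
    records: Iterable[SamRecord],
    truths: Sequence[TruthRecord],
    min_intron: int = DEFAULT_MIN_INTRON,
) -> SpliceConfusion:
    truth_by_id, rec_by_id = _pair_records(records, truths)
    conf = SpliceConfusion()
    for rid, t in truth_by_id.items():
        true_j = set(t.junctions(min_intron))
        rec = rec_by_id.get(rid)
        if rec is None or rec.is_unmapped:
            conf.fn += len(true_j)
            continue
        if rec.rname == t.rname:
            pred_j = set(predicted_junctions(rec))
        else:
            pred_j = set()
            conf.fp += len(predicted_junctions(rec))
        conf.tp += len(true_j & pred_j)
        conf.fn += len(true_j - pred_j)
        conf.fp += len(pred_j - true_j)
    return conf


def splice_metrics(
    records: Iterable[SamRecord],
    truths: Sequence[TruthRecord],
    min_intron: int = DEFAULT_MIN_INTRON,
) -> tuple[float, float]:
    """(recall, FDR) over splices; FDR is 0 when nothing was predicted."""
    conf = splice_confusion(records, truths, min_intron)
    return conf.recall, conf.fdr


# ---------------------------------------------------------------------------
# Read categories
# ---------------------------------------------------------------------------

def read_categories(
    records: Iterable[SamRecord],
    truths: Sequence[TruthRecord],
    min_intron: int = DEFAULT_MIN_INTRON,
) -> dict[str, Counter]:
    """Counts of perfectly / part / incorrectly mapped and unmapped reads.

    Perfect requires every read base's placement (a reference position, or
    none for inserted bases) to equal the truth placement; soft-clipped bases
    count as not placed.  Reported for all reads and for the spliced /
    unspliced subsets.
    """
    truth_by_id, rec_by_id = _pair_records(records, truths)
    out = {"all": Counter(), "spliced": Counter(), "unspliced": Counter()}
    for rid, t in truth_by_id.items():
        rec = rec_by_id.get(rid)
        groups = ["all", "spliced" if t.n_junctions(min_intron) else "unspliced"]
        if rec is None or rec.is_unmapped:
            cat = "unmapped"
        else:
            tmap = truth_base_map(t, len(rec.seq))
            pmap = predicted_base_map(rec)
            if rec.rname != t.rname:
                correct = 0
                exact = False
            else:
                correct = sum(
                    1 for a, b in zip(pmap, tmap) if a is not None and a == b
                )
                exact = all(a == b for a, b in zip(pmap, tmap))
            if exact:
                cat = "perfect"
            elif correct > 0:
                cat = "part"
            else:
                cat = "none"
        for g in groups:
            out[g][cat] += 1
    return out


# ---------------------------------------------------------------------------
# Multi-junction tally
# ---------------------------------------------------------------------------

@dataclass
class JunctionCountTally:
    tp: Counter
    fp: Counter
    fn: Counter

    def metrics(self, k: int) -> tuple[Optional[float], Optional[float], Optional[float]]:
        tp, fp, fn = self.tp[k], self.fp[k], self.fn[k]
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        f = (
            fmeasure(precision, recall)
            if precision is not None and recall is not None
            else None
        )
        return precision, recall, f


def multi_junction_tally(
    records: Iterable[SamRecord],
    truths: Sequence[TruthRecord],
    min_intron: int = DEFAULT_MIN_INTRON,
) -> JunctionCountTally:
    """Per-junction-count read bookkeeping.

    A read is a true positive for its true junction count k when all k
    junctions are recovered exactly and none are added.  Predicting a
    different count k' scores a false negative at k and a false positive at
    k'; the right count with wrong coordinates scores a false positive (and
    a missed read, i.e. false negative) at k.  Indel gaps are ignored.
    """
    truth_by_id, rec_by_id = _pair_records(records, truths)
    tally = JunctionCountTally(Counter(), Counter(), Counter())
    for rid, t in truth_by_id.items():
        true_j = set(t.junctions(min_intron))
        k = len(true_j)
        rec = rec_by_id.get(rid)
        if rec is None or rec.is_unmapped:
            tally.fn[k] += 1
            continue
        pred_j = set(predicted_junctions(rec)) if rec.rname == t.rname else set()
        kp = (
            len(predicted_junctions(rec))
            if rec.rname == t.rname
            else len(predicted_junctions(rec))
        )
        if kp != k:
            tally.fn[k] += 1
            tally.fp[kp] += 1
        elif pred_j == true_j:
            tally.tp[k] += 1
        else:
            tally.fp[k] += 1
            tally.fn[k] += 1
    return tally


def fmeasure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not 0 <= precision <= 1 or not 0 <= recall <= 1:
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Indel metrics
# ---------------------------------------------------------------------------

def indel_metrics(
    records: Iterable[SamRecord],
    truths: Sequence[TruthRecord],
    max_size: int = 10,
) -> dict[tuple[str, int], dict[str, Optional[float]]]:
    """Per-type, per-size indel confusion and precision/recall/F.

    A predicted indel matches only at the exact reference position with the
    exact type and length.  Cells where nothing of that size was predicted
    have precision and F undefined (None); recall is None only when nothing
    of that size was simulated.
    """
    truth_by_id, rec_by_id = _pair_records(records, truths)
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    for rid, t in truth_by_id.items():
        true_events = {(ev.kind, ev.ref_pos, ev.length) for ev in t.indels}
        rec = rec_by_id.get(rid)
        if rec is None or rec.is_unmapped or rec.rname != t.rname:
            pred_events = set()
        else:
            pred_events = set(predicted_indels(rec))
        if rec is not None and not rec.is_unmapped and rec.rname != t.rname:
            for kind, _pos, n in predicted_indels(rec):
                fp[(kind, n)] += 1
        for ev in true_events & pred_events:
            tp[(ev[0], ev[2])] += 1
        for ev in true_events - pred_events:
            fn[(ev[0], ev[2])] += 1
        for ev in pred_events - true_events:
            fp[(ev[0], ev[2])] += 1
    out: dict[tuple[str, int], dict[str, Optional[float]]] = {}
    for kind in "ID":
        for size in range(1, max_size + 1):
            key = (kind, size)
            t_, f_, n_ = tp[key], fp[key], fn[key]
            precision = t_ / (t_ + f_) if t_ + f_ else None
            recall = t_ / (t_ + n_) if t_ + n_ else None
            f = (
                fmeasure(precision, recall)
                if precision is not None and recall is not None
                else None
            )
            out[key] = {
                "tp": t_,
                "fp": f_,
                "fn": n_,
                "precision": precision,
                "recall": recall,
                "f": f,
            }
    return out


def overall_indel_recall(
    metrics: dict[tuple[str, int], dict[str, Optional[float]]]
) -> float:
    tp = sum(m["tp"] for m in metrics.values())
    fn = sum(m["fn"] for m in metrics.values())
    return tp / (tp + fn) if tp + fn else 0.0


# ---------------------------------------------------------------------------
# Anchoring helper (which truth reads a mapper can be expected to place)
# ---------------------------------------------------------------------------

def well_anchored(
    rec: TruthRecord, min_flank: int, min_intron: int = DEFAULT_MIN_INTRON
) -> bool:
    """Whether every junction of a truth read has >= min_flank anchored bases.

    Unspliced reads are always well anchored.  The first and last reference
    blocks bound the read bases available on the outer sides of the
    outermost junctions.
    """
    if rec.n_junctions(min_intron) == 0:
        return True
    first = rec.blocks[0]
    last = rec.blocks[-1]
    return (first[1] - first[0]) >= min_flank and (last[1] - last[0]) >= min_flank
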