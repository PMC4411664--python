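import numpy as np
import pytest

from splicemap import evaluation as ev
from splicemap.model import IndelEvent, SamRecord, TruthRecord


def _truth(rid, blocks, strand="+", mism=(), indels=()):
    return TruthRecord(rid, "chr1", strand, tuple(blocks), tuple(mism), tuple(indels))


def _rec(rid, pos, cigar, strand="+", l=None):
    if cigar == "*":
        return SamRecord(rid, 4, "*", -1, 0, "*", "A" * 76, "I" * 76)
    if l is None:
        l = sum(n for n, op in __import__("splicemap.io_formats", fromlist=["iter_cigar"]).iter_cigar(cigar) if op in "MIS")
    return SamRecord(rid, 16 if strand == "-" else 0, "chr1", pos, 255, cigar,
                     "A" * l, "I" * l)


class TestSpliceMetrics:
    def test_all_recovered(self):
        truths = [_truth("r1", [(0, 40), (140, 176)])]
        recs = [_rec("r1", 0, "40M100N36M")]
        assert ev.splice_metrics(recs, truths) == (1.0, 0.0)

    def test_nine_of_ten_plus_one_spurious(self):
        truths = [_truth(f"r{i}", [(0, 40), (140, 176)]) for i in range(10)]
        recs = [_rec(f"r{i}", 0, "40M100N36M") for i in range(9)]
        # the tenth read predicts a different (spurious) junction
        recs.append(_rec("r9", 0, "30M200N46M"))
        recall, fdr = ev.splice_metrics(recs, truths)
        assert recall == pytest.approx(0.9)
        assert fdr == pytest.approx(0.1)

    def test_zero_predictions(self):
        truths = [_truth("r1", [(0, 40), (140, 176)])]
        recs = [_rec("r1", 0, "*")]
        assert ev.splice_metrics(recs, truths) == (0.0, 0.0)

    def test_unknown_read_id_error(self):
        truths = [_truth("r1", [(0, 76)])]
        with pytest.raises(ValueError, match="unknown"):
            ev.splice_metrics([_rec("zz", 0, "76M")], truths)

    def test_order_invariance(self):
        truths = [_truth(f"r{i}", [(0, 40), (140, 176)]) for i in range(6)]
        recs = [_rec(f"r{i}", 0, "40M100N36M") for i in range(6)]
        fwd = ev.splice_metrics(recs, truths)
        rev = ev.splice_metrics(list(reversed(recs)), truths)
        assert fwd == rev


class TestReadCategories:
    def test_clean_regime_all_perfect(self):
        truths = [_truth("r1", [(10, 86)]), _truth("r2", [(0, 40), (140, 176)])]
        recs = [_rec("r1", 10, "76M"), _rec("r2", 0, "40M100N36M")]
        cats = ev.read_categories(recs, truths)
        assert cats["all"]["perfect"] == 2
        assert cats["all"].get("part", 0) == 0

    def test_wrong_copy_counts_none(self):
        truths = [_truth("r1", [(10, 86)])]
        recs = [_rec("r1", 5000, "76M")]
        cats = ev.read_categories(recs, truths)
        assert cats["all"]["none"] == 1

    def test_half_right_split_counts_part(self):
        truths = [_truth("r1", [(0, 40), (140, 176)])]
        recs = [_rec("r1", 0, "40M300N36M")]  # right block at the wrong acceptor
        cats = ev.read_categories(recs, truths)
        assert cats["spliced"]["part"] == 1

    def test_soft_clip_blocks_perfect(self):
        truths = [_truth("r1", [(10, 86)])]
        recs = [_rec("r1", 20, "10S66M")]
        cats = ev.read_categories(recs, truths)
        assert cats["all"]["part"] == 1

    def test_reverse_strand_perfect(self):
        truths = [_truth("r1", [(10, 86)], strand="-")]
        recs = [_rec("r1", 10, "76M", strand="-")]
        assert ev.read_categories(recs, truths)["all"]["perfect"] == 1


class TestMultiJunctionTally:
    def test_true_positive(self):
        truths = [_truth("r1", [(0, 30), (130, 160), (260, 276)])]
        recs = [_rec("r1", 0, "30M100N30M100N16M")]
        tally = ev.multi_junction_tally(recs, truths)
        assert tally.tp[2] == 1 and tally.fn[2] == 0

    def test_count_mismatch_fn_plus_fp(self):
        truths = [_truth("r1", [(0, 30), (130, 160), (260, 276)])]
        recs = [_rec("r1", 0, "30M100N46M")]  # predicted one junction, true two
        tally = ev.multi_junction_tally(recs, truths)
        assert tally.fn[2] == 1 and tally.fp[1] == 1

    def test_right_count_wrong_site(self):
        truths = [_truth("r1", [(0, 30), (130, 160), (260, 276)])]
        recs = [_rec("r1", 0, "30M100N30M110N16M")]
        tally = ev.multi_junction_tally(recs, truths)
        assert tally.fp[2] == 1 and tally.fn[2] == 1 and tally.tp[2] == 0

    def test_indel_gaps_ignored(self):
        truths = [
            _truth("r1", [(0, 30), (35, 81)],
                   indels=(IndelEvent("D", 30, 5, 30),))
        ]
        recs = [_rec("r1", 0, "30M5D46M")]
        tally = ev.multi_junction_tally(recs, truths)
        assert tally.tp[0] == 1

    def test_tally_conservation(self):
        rng = np.random.default_rng(2)
        truths, recs = [], []
        for i in range(50):
            k = int(rng.integers(0, 3))
            blocks = []
            pos = 0
            remaining = 76
            for j in range(k + 1):
                blen = remaining // (k + 1 - j) if j < k else remaining
                blocks.append((pos, pos + blen))
                pos += blen + 200
                remaining -= blen
            truths.append(_truth(f"r{i}", blocks))
            if rng.random() < 0.3:
                recs.append(_rec(f"r{i}", 0, "*"))
            else:
                cigar = "".join(
                    f"{e - s}M" + ("200N" if j < len(blocks) - 1 else "")
                    for j, (s, e) in enumerate(blocks)
                )
                recs.append(_rec(f"r{i}", 0, cigar))
        tally = ev.multi_junction_tally(recs, truths)
        spliced = sum(1 for t in truths if t.n_junctions() >= 1)
        assert sum(
            tally.tp[k] + tally.fn[k] for k in set(tally.tp) | set(tally.fn) if k >= 1
        ) == spliced


class TestFMeasure:
    def test_symmetry(self):
        assert ev.fmeasure(0.5, 0.5) == pytest.approx(0.5)

    def test_degenerate(self):
        assert ev.fmeasure(1.0, 0.0) == 0.0
        assert ev.fmeasure(0.0, 0.0) == 0.0

    def test_direct_value(self):
        assert ev.fmeasure(0.9, 0.8) == pytest.approx(0.8470588235294118)

    def test_bounds(self):
        with pytest.raises(ValueError):
            ev.fmeasure(1.2, 0.5)


class TestIndelMetrics:
    def test_exact_deletion_recovered(self):
        truths = [
            _truth("r1", [(0, 30), (33, 79)], indels=(IndelEvent("D", 30, 3, 30),))
        ]
        recs = [_rec("r1", 0, "30M3D46M")]
        m = ev.indel_metrics(recs, truths)
        assert m[("D", 3)]["recall"] == 1.0 and m[("D", 3)]["precision"] == 1.0

    def test_off_by_one_counts_fp_and_fn(self):
        truths = [
            _truth("r1", [(0, 30), (33, 79)], indels=(IndelEvent("D", 30, 3, 30),))
        ]
        recs = [_rec("r1", 0, "29M3D47M")]
        m = ev.indel_metrics(recs, truths)
        assert m[("D", 3)]["fp"] == 1 and m[("D", 3)]["fn"] == 1

    def test_unpredicted_size_undefined(self):
        truths = [_truth("r1", [(0, 76)])]
        recs = [_rec("r1", 0, "76M")]
        m = ev.indel_metrics(recs, truths)
        assert m[("I", 9)]["precision"] is None and m[("I", 9)]["recall"] is None


class TestBruteForceOracle:
    def test_randomized_agreement(self):
        """splice metrics and junction tallies match an independent
        brute-force confusion builder over randomized prediction/truth pairs."""
        rng = np.random.default_rng(33)
        junction_pool = [(100 * i, 100 * i + 60) for i in range(1, 30)]
        truths, recs = [], []
        for i in range(400):
            k = int(rng.integers(0, 4))
            juncs = sorted(
                junction_pool[j]
                for j in rng.choice(len(junction_pool), size=k, replace=False)
            )
            blocks = []
            pos = juncs[0][0] - 20 if juncs else int(rng.integers(0, 1000))
            start = pos
            for a, b in juncs:
                blocks.append((start, a))
                start = b
            blocks.append((start, start + 20))
            truths.append(_truth(f"r{i}", blocks))
            if rng.random() < 0.15:
                recs.append(_rec(f"r{i}", 0, "*"))
                continue
            # predicted junctions: drop or swap some
            pred = [
                j for j in juncs if rng.random() > 0.2
            ]
            if rng.random() < 0.2:
                extra = junction_pool[int(rng.integers(0, len(junction_pool)))]
                pred = sorted(set(pred) | {extra})
            pstart = pred[0][0] - 20 if pred else blocks[0][0]
            cigar = ""
            cursor = pstart
            for a, b in pred:
                cigar += f"{a - cursor}M{b - a}N"
                cursor = b
            cigar += "20M"
            recs.append(_rec(f"r{i}", pstart, cigar))
        # brute-force confusion
        tp = fp = fn = 0
        rec_by = {r.qname: r for r in recs}
        for t in truths:
            r = rec_by[t.read_id]
            true_j = set(t.junctions())
            pred_j = set() if r.is_unmapped else set(ev.predicted_junctions(r))
            tp += len(true_j & pred_j)
            fn += len(true_j - pred_j)
            fp += len(pred_j - true_j)
        recall, fdr = ev.splice_metrics(recs, truths)
        assert recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
        assert fdr == pytest.approx(fp / (tp + fp) if tp + fp else 0.0)
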