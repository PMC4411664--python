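import numpy as np
import pytest

from splicemap import split_discovery as sd
from splicemap.model import RawAlignment, ReferenceSequence
from splicemap.params import MappingParams
from splicemap.seed_aligner import build_index, align_anchored, align_local, classify
from splicemap.model import Read


def _cand(ref_start, length=76, rname="chr1", anchor="start", kind="single",
          oriented="A" * 76, read_start=0, read_end=None, mismatches=()):
    read_end = read_end if read_end is not None else len(oriented)
    raw = RawAlignment(
        read_id="r", rname=rname, strand="+", ref_start=ref_start,
        read_start=read_start, read_end=read_end, read_length=len(oriented),
        mismatches=tuple(mismatches), end_to_end=(read_start == 0 and read_end == len(oriented)),
        seed_anchor=anchor,
    )
    return sd.Candidate(raw, oriented, kind)


class TestBuildWindows:
    def test_single_candidate_single_window(self):
        wins = sd.build_windows([_cand(100)], 10_000)
        assert len(wins) == 1
        assert wins[0].start == 100 and wins[0].members[0].raw.ref_start == 100

    def test_window_cap_rule(self):
        """Candidates at 0/100/200 (76 nt) with max length 250: the first
        window admits all three (they start before the cap) and spans to 276;
        the candidate at 200 is not contained within the cap and opens the
        next window."""
        cands = [_cand(0), _cand(100), _cand(200)]
        wins = sd.build_windows(cands, 250)
        assert len(wins) == 2
        assert (wins[0].start, wins[0].end) == (0, 276)
        assert len(wins[0].members) == 3
        assert wins[1].start == 200

    def test_chromosomes_never_mixed(self):
        cands = [_cand(100, rname="chr1"), _cand(120, rname="chr2")]
        wins = sd.build_windows(cands, 10_000)
        assert len(wins) == 2
        assert {w.rname for w in wins} == {"chr1", "chr2"}

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        cands = [_cand(int(p)) for p in rng.integers(0, 50_000, size=40)]
        wins_a = sd.build_windows(cands, 5_000)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        wins_b = sd.build_windows(shuffled, 5_000)
        key = lambda ws: [(w.rname, w.start, w.end, len(w.members)) for w in ws]
        assert key(wins_a) == key(wins_b)

    def test_every_candidate_in_some_window(self):
        rng = np.random.default_rng(9)
        cands = [_cand(int(p)) for p in rng.integers(0, 30_000, size=30)]
        wins = sd.build_windows(cands, 2_000)
        members = {id(c) for w in wins for c in w.members}
        assert members == {id(c) for c in cands}


class TestWindowSequence:
    refs = {"chr1": "ACGT" * 5_000}  # 20 kb

    def test_no_edge_candidate_plain_window(self):
        w = sd.SlidingWindow("chr1", 5_000, 15_000, 12_000,
                            [_cand(8_000, anchor="start")])
        seq, origin = sd.window_sequence(w, self.refs, x=1_000)
        assert origin == 5_000 and len(seq) == 7_000

    def test_downstream_extension_for_start_anchored(self):
        w = sd.SlidingWindow("chr1", 5_000, 15_000, 6_000,
                            [_cand(5_900, anchor="start")])
        seq, origin = sd.window_sequence(w, self.refs, x=1_000)
        assert origin == 5_000
        assert origin + len(seq) == 7_000  # 6 000 + x

    def test_upstream_extension_for_end_anchored(self):
        w = sd.SlidingWindow("chr1", 5_000, 15_000, 6_000,
                            [_cand(5_050, anchor="end")])
        seq, origin = sd.window_sequence(w, self.refs, x=1_000)
        assert origin == 4_000

    def test_extension_clipped_at_chromosome_start(self):
        w = sd.SlidingWindow("chr1", 300, 10_300, 500, [_cand(350, anchor="end")])
        seq, origin = sd.window_sequence(w, self.refs, x=1_000)
        assert origin == 0


@pytest.fixture(scope="module")
def split_world():
    """A deterministic random reference with canonical splice motifs written
    at the intron boundaries used by the fixtures (mirrors the simulator, so
    junction coordinates are not shift-ambiguous)."""
    rng = np.random.default_rng(42)
    seq = list("".join(rng.choice(list("ACGT"), size=6_000)))
    for istart, iend in [(1040, 1240), (3025, 3200), (3226, 3400)]:
        seq[istart], seq[istart + 1] = "G", "T"
        seq[iend - 2], seq[iend - 1] = "A", "G"
    return ReferenceSequence("chr1", "".join(seq))


class TestCompleteSingleSplit:
    def _complete(self, genome, read_seq, params, anchor="start"):
        idx = build_index([genome], params.seed_len)
        read = Read("r", read_seq)
        raws = align_anchored(read, idx, params.max_mismatches, 10, anchor)
        out = []
        win_index = sd.build_window_index(
            genome.sequence, 0, len(genome.sequence), params.window_seed_len
        )
        for raw in raws:
            cand = sd.Candidate(raw, read_seq, "single")
            out += sd.complete_single_split(cand, genome.sequence, win_index, params)
        return out

    def test_intron_200(self, split_world, params):
        g = split_world.sequence
        read = g[1000:1040] + g[1240:1276]
        alns = self._complete(split_world, read, params)
        assert any(
            a.blocks == ((1000, 1040, 0, 40), (1240, 1276, 40, 76))
            and a.mismatch_count == 0
            for a in alns
        )

    def test_illegal_gap_30_not_determined(self, split_world, params):
        g = split_world.sequence
        read = g[1000:1040] + g[1070:1106]  # gap 30: > max deletion, < min intron
        alns = self._complete(split_world, read, params)
        assert not any(
            a.gap_sizes() == [30] for a in alns
        )

    def test_deletion_5(self, split_world, params):
        g = split_world.sequence
        read = g[2000:2040] + g[2045:2081]
        alns = self._complete(split_world, read, params)
        assert any(a.gap_sizes() == [5] for a in alns)

    def test_no_completion_empty(self, split_world, params):
        g = split_world.sequence
        read = g[1000:1040] + "TGCA" * 9  # alien tail
        alns = self._complete(split_world, read, params)
        assert all(a.mismatch_count <= params.max_mismatches for a in alns)


class TestMakeFragments:
    def _local(self, i0, j0, l=76):
        return RawAlignment(
            read_id="r", rname="c", strand="+", ref_start=500 + i0,
            read_start=i0, read_end=j0, read_length=l, mismatches=(),
            end_to_end=False, seed_anchor="start",
        )

    def test_long_prefix_short_suffix(self):
        # 1-based i=31, j=60: prefix 30 >= e -> f1 = r11..r60 (50 nt);
        # suffix 16 < e -> f2 = r31..r76 (46 nt)
        f1, f2 = sd.make_fragments(self._local(30, 60), "A" * 76, e=20)
        assert (f1.read_offset, len(f1.sequence)) == (10, 50)
        assert (f2.read_offset, len(f2.sequence)) == (30, 46)

    def test_short_prefix_truncated(self):
        # 1-based i=6: prefix 5 < e -> f1 = r1..r60
        f1, _f2 = sd.make_fragments(self._local(5, 60), "A" * 76, e=20)
        assert (f1.read_offset, len(f1.sequence)) == (0, 60)

    def test_both_formulas(self):
        # 1-based i=21, j=56 -> f1 = r1..r56, f2 = r21..r76
        f1, f2 = sd.make_fragments(self._local(20, 56), "A" * 76, e=20)
        assert (f1.read_offset, len(f1.sequence)) == (0, 56)
        assert (f2.read_offset, len(f2.sequence)) == (20, 56)

    def test_full_read_alignment_rejected(self):
        with pytest.raises(ValueError):
            sd.make_fragments(self._local(0, 76), "A" * 76, e=20)


class TestFragmentSingleSplits:
    def test_three_exon_read(self, split_world, params):
        g = split_world.sequence
        # exons: [3000,3025) [3200,3226) [3400,3425); read = 25+26+25
        read_seq = g[3000:3025] + g[3200:3226] + g[3400:3425]
        idx = build_index([split_world], params.local_seed_len)
        read = Read("r", read_seq)
        locs = [
            a for a in align_local(read, idx, params.local_seed_len)
            if a.read_start > 0 and a.read_end < 76
        ]
        assert locs, "middle exon should be found as a local block"
        win_index = sd.build_window_index(g, 2_500, 4_000, params.window_seed_len)
        out = []
        for raw in locs:
            out += sd.fragment_single_splits(
                sd.Candidate(raw, read_seq, "multi"), g, win_index, params
            )
        sides = {a.fragment_side for a in out}
        assert sides == {"f1", "f2"}
        f1 = [a for a in out if a.fragment_side == "f1"][0]
        f2 = [a for a in out if a.fragment_side == "f2"][0]
        assert (3025, 3200) in [(d, a_) for d, a_, _ in f1.gaps()]
        assert (3226, 3400) in [(d, a_) for d, a_, _ in f2.gaps()]

    def test_split_reconstructs_read(self, split_world, params):
        """Concatenating reference block sequences reproduces the read up to
        the recorded mismatch count."""
        g = split_world.sequence
        read_seq = g[1000:1040] + g[1240:1276]
        idx = build_index([split_world], params.seed_len)
        raws = align_anchored(Read("r", read_seq), idx, 4, 10, "start")
        win_index = sd.build_window_index(g, 0, len(g), params.window_seed_len)
        for raw in raws:
            for a in sd.complete_single_split(
                sd.Candidate(raw, read_seq, "single"), g, win_index, params
            ):
                rebuilt = []
                for rs, re_, qs, qe in a.blocks:
                    rebuilt.append(g[rs:re_])
                joined = "".join(rebuilt)
                covered = "".join(
                    read_seq[qs:qe] for _rs, _re, qs, qe in a.blocks
                )
                diffs = sum(1 for x, y in zip(joined, covered) if x != y)
                assert diffs == a.mismatch_count
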