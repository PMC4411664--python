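import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicemap import resolution as rn
from splicemap.model import Context, GapType, SplitAlignment, SpliceSite
from splicemap.params import MappingParams


class TestEvidenceScore:
    def test_two_clean_one_noisy(self):
        assert rn.evidence_score([2, 1, 0, 0, 0], 0.3) == pytest.approx(2.3)

    def test_all_zero(self):
        assert rn.evidence_score([0, 0, 0, 0, 0], 0.3) == 0.0

    def test_single_four_mismatch_supporter(self):
        assert rn.evidence_score([0, 0, 0, 0, 1], 0.3) == pytest.approx(0.3**4)

    def test_w_out_of_range(self):
        with pytest.raises(ValueError):
            rn.evidence_score([1], 1.0)
        with pytest.raises(ValueError):
            rn.evidence_score([1], 0.0)

    @given(
        st.lists(st.integers(0, 500), min_size=5, max_size=5),
        st.sampled_from([0.1, 0.3, 0.9]),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence(self, counts, w):
        """Term-by-term independent summation agrees to 1e-12 relative."""
        expected = 0.0
        for i in range(4, -1, -1):  # reversed order: independent accumulation
            expected += (w**i) * counts[i]
        got = rn.evidence_score(counts, w)
        assert got == pytest.approx(expected, rel=1e-12)


class TestClassifyGap:
    @pytest.mark.parametrize(
        "gap,expected",
        [
            (-3, GapType.INSERTION),
            (-10, GapType.INSERTION),
            (-11, None),
            (1, GapType.DELETION),
            (5, GapType.DELETION),
            (10, GapType.DELETION),
            (11, None),
            (30, None),
            (49, None),
            (50, GapType.INTRON),
            (100, GapType.INTRON),
            (300_000, GapType.INTRON),
            (300_001, None),
        ],
    )
    def test_printed_boundaries(self, gap, expected):
        assert rn.classify_gap(gap) is expected

    def test_zero_gap_error(self):
        with pytest.raises(ValueError):
            rn.classify_gap(0)

    def test_total_and_exclusive_on_sample(self):
        rng = np.random.default_rng(0)
        for g in rng.integers(-300_001, 300_002, size=5_000):
            g = int(g)
            if g == 0:
                continue
            kinds = [
                k
                for k, ok in [
                    (GapType.INSERTION, -10 <= g <= -1),
                    (GapType.DELETION, 1 <= g <= 10),
                    (GapType.INTRON, 50 <= g <= 300_000),
                ]
                if ok
            ]
            got = rn.classify_gap(g)
            assert got == (kinds[0] if kinds else None)


def _site(donor, acceptor, read_gap=0):
    return SpliceSite("chr1", donor, acceptor, read_gap)


class TestSelectBestSites:
    def test_group_of_two_both_retained(self):
        counts = {_site(100, 500): [2, 0, 0, 0, 0], _site(100, 600): [1, 0, 0, 0, 0]}
        retained = rn.select_best_sites(counts, 0.3)
        assert retained == set(counts)

    def test_top_three_of_five(self):
        # evidence 5.0, 3.3, 1.3, then a 1.0 tie at third-from-last place:
        # only three sites survive and the tie goes to the leftmost donor
        sites = [
            (_site(100, 500), [5, 0, 0, 0, 0]),
            (_site(100, 510), [3, 1, 0, 0, 0]),
            (_site(104, 520), [1, 0, 0, 0, 0]),
            (_site(106, 530), [1, 0, 0, 0, 0]),
        ]
        retained = rn.select_best_sites(dict(sites), 0.3)
        assert len(retained) == 3
        assert sites[0][0] in retained and sites[1][0] in retained
        assert sites[2][0] in retained and sites[3][0] not in retained

    def test_disjoint_sites_all_retained(self):
        counts = {
            _site(100, 500): [1, 0, 0, 0, 0],
            _site(1000, 1500): [1, 0, 0, 0, 0],
            _site(2000, 2500): [1, 0, 0, 0, 0],
            _site(3000, 3500): [1, 0, 0, 0, 0],
        }
        assert rn.select_best_sites(counts, 0.3) == set(counts)

    def test_long_false_interval_does_not_chain_groups(self):
        """A huge interval overlapping many strong sites must not drag
        unrelated weak-but-unopposed sites out of the retained set."""
        counts = {_site(0, 100_000): [1, 0, 0, 0, 0]}
        strong = [_site(1000 * i, 1000 * i + 500) for i in range(1, 8)]
        for s in strong:
            counts[s] = [10, 0, 0, 0, 0]
        retained = rn.select_best_sites(counts, 0.3)
        assert set(strong) <= retained

    def test_alignment_using_discarded_site_detected(self):
        retained = {_site(100, 500)}
        good = SplitAlignment(
            "r", "chr1", "+", ((60, 100, 0, 40), (500, 536, 40, 76)), 0, 76
        )
        bad = SplitAlignment(
            "r", "chr1", "+", ((60, 100, 0, 40), (600, 636, 40, 76)), 0, 76
        )
        assert rn.uses_only_sites(good, retained)
        assert not rn.uses_only_sites(bad, retained)


class TestAnnotationBonus:
    def test_annotated_site_boosted(self):
        site = _site(100, 500)
        assert rn.annotation_bonus(site, 2.3, {("chr1", 100, 500)}, 1.0) == 3.3

    def test_unannotated_unchanged(self):
        site = _site(100, 501)
        assert rn.annotation_bonus(site, 2.3, {("chr1", 100, 500)}, 1.0) == 2.3

    def test_zero_bonus_noop(self):
        site = _site(100, 500)
        assert rn.annotation_bonus(site, 2.3, {("chr1", 100, 500)}, 0.0) == 2.3


def _member(rid, start, length=76, blocks=None, subs=0):
    if blocks is None:
        blocks = ((start, start + length, 0, length),)
    return SplitAlignment(rid, "chr1", "+", tuple(blocks), subs, 76)


class TestSupportScore:
    def test_alone_in_context_scores_self_coverage(self, params):
        a = _member("r1", 1000)
        prof = rn.CoverageProfile.from_alignments("chr1", 900, 1200, [a])
        s = rn.support_score(a, prof, params)
        assert s.value == pytest.approx(params.support_lambda_in * 1.0)

    def test_pile_beats_isolated_alternative(self, params):
        pile = [_member(f"p{i}", 1000 + 3 * i) for i in range(10)]
        target_in_pile = _member("t", 1010)
        target_alone = _member("t", 5000)
        prof = rn.CoverageProfile.from_alignments("chr1", 900, 6000, pile)
        s_pile = rn.support_score(target_in_pile, prof, params)
        s_alone = rn.support_score(target_alone, prof, params)
        assert s_pile.value > s_alone.value

    def test_monotone_under_added_coverage(self, params):
        """Adding a concordant overlapping read never decreases support."""
        base = [_member(f"p{i}", 1000 + 5 * i) for i in range(5)]
        target = _member("t", 1010)
        prof1 = rn.CoverageProfile.from_alignments("chr1", 800, 1400, base)
        prof2 = rn.CoverageProfile.from_alignments(
            "chr1", 800, 1400, base + [_member("new", 1005)]
        )
        assert (
            rn.support_score(target, prof2, params).value
            >= rn.support_score(target, prof1, params).value
        )


class TestResolveLocal:
    def test_argmax_support(self, params):
        pile = [_member(f"p{i}", 1000) for i in range(8)]
        v1 = _member("t", 1000)   # inside the pile
        v2 = _member("t", 3000)   # isolated
        ctx = Context(0, "chr1", 900, 3200, pile + [v1, v2])
        chosen = rn.resolve_local(ctx, params)
        assert chosen["t"].ref_start == 1000

    def test_single_placement_chosen(self, params):
        a = _member("t", 1000)
        ctx = Context(0, "chr1", 900, 1200, [a])
        assert rn.resolve_local(ctx, params)["t"] is a

    def test_equal_support_fewer_mismatches_wins(self, params):
        v1 = _member("t", 1000, subs=1)
        v2 = _member("t", 1000, subs=3)
        ctx = Context(0, "chr1", 900, 1200, [v1, v2])
        assert rn.resolve_local(ctx, params)["t"].mismatch_count == 1


class TestMergeFragmentSplits:
    def _make_world(self):
        rng = np.random.default_rng(7)
        g = list("".join(rng.choice(list("ACGT"), size=3000)))
        return "".join(g)

    def test_consistent_merge(self, params):
        g = self._make_world()
        # exons [1000,1025) [1200,1226) [1400,1425): read 25+26+25
        read = g[1000:1025] + g[1200:1226] + g[1400:1425]
        f1 = SplitAlignment("r", "chr1", "+",
                            ((1005, 1025, 5, 25), (1200, 1226, 25, 51)),
                            0, 76, source="fragment", fragment_side="f1")
        f2 = SplitAlignment("r", "chr1", "+",
                            ((1200, 1226, 25, 51), (1400, 1420, 51, 71)),
                            0, 76, source="fragment", fragment_side="f2")
        merged = rn.merge_fragment_splits(f1, f2, read, g, params)
        assert merged is not None
        assert len(merged.blocks) == 3
        assert merged.blocks[1] == (1200, 1226, 25, 51)

    def test_short_internal_exon_rejected(self, params):
        g = self._make_world()
        read = g[1000:1025] + g[1200:1215] + g[1400:1436]
        f1 = SplitAlignment("r", "chr1", "+",
                            ((1005, 1025, 5, 25), (1200, 1215, 25, 40)),
                            0, 76, source="fragment", fragment_side="f1")
        f2 = SplitAlignment("r", "chr1", "+",
                            ((1200, 1215, 25, 40), (1400, 1420, 40, 60)),
                            0, 76, source="fragment", fragment_side="f2")
        assert rn.merge_fragment_splits(f1, f2, read, g, params) is None

    def test_inconsistent_middle_no_merge(self, params):
        g = self._make_world()
        read = "A" * 76
        f1 = SplitAlignment("r", "chr1", "+",
                            ((1005, 1025, 5, 25), (1200, 1226, 25, 51)),
                            0, 76, source="fragment", fragment_side="f1")
        f2 = SplitAlignment("r", "chr1", "+",
                            ((1300, 1326, 25, 51), (1500, 1520, 51, 71)),
                            0, 76, source="fragment", fragment_side="f2")
        assert rn.merge_fragment_splits(f1, f2, read, g, params) is None

    def test_different_reads_error(self, params):
        g = self._make_world()
        f1 = SplitAlignment("r1", "chr1", "+",
                            ((1005, 1025, 5, 25), (1200, 1226, 25, 51)), 0, 76,
                            fragment_side="f1")
        f2 = SplitAlignment("r2", "chr1", "+",
                            ((1200, 1226, 25, 51), (1400, 1420, 51, 71)), 0, 76,
                            fragment_side="f2")
        with pytest.raises(ValueError):
            rn.merge_fragment_splits(f1, f2, "A" * 76, g, params)


class TestResolveGlobal:
    def test_argmax_across_contexts(self, params):
        pile_a = [_member(f"a{i}", 1000) for i in range(9)]
        choice_a = {m.read_id: m for m in pile_a}
        v_a = _member("t", 1000)
        choice_a["t"] = v_a
        ctx_a = Context(0, "chr1", 900, 1200, pile_a + [v_a])
        v_b = _member("t", 50_000)
        ctx_b = Context(1, "chr1", 49_900, 50_200, [v_b])
        choice_b = {"t": v_b}
        final = rn.resolve_global([ctx_a, ctx_b], [choice_a, choice_b], params)
        assert final["t"] is v_a

    def test_single_context_read_kept(self, params):
        v = _member("t", 1000)
        ctx = Context(0, "chr1", 900, 1200, [v])
        final = rn.resolve_global([ctx], [{"t": v}], params)
        assert final["t"] is v
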