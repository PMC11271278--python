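import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapi.annotate import (
    AnchorAnnotation,
    EPLoop,
    LoopClass,
    annotate_anchors,
    classify_loop,
    extract_ep_loops,
    filter_loops,
)
from hapi.io import GenomicInterval, Loop, TSSRecord


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def mk_loop(c1, s1, c2, s2, pets=5, width=2000):
    return Loop(iv(c1, s1, s1 + width), iv(c2, s2, s2 + width), pets)


class TestFilterLoops:
    def test_pet_threshold(self):
        loops = [mk_loop("chr1", 10000, "chr1", 50000, pets=p) for p in (1, 2, 3, 5)]
        kept, report = filter_loops(loops, [])
        assert len(kept) == 2
        assert sorted(lp.pets for lp in kept) == [3, 5]
        assert report.pet_removed == 2

    def test_one_bp_blacklist_overlap_removes(self):
        loop = mk_loop("chr1", 10000, "chr1", 50000)
        # blacklist interval overlapping anchor1 by exactly 1 bp
        kept, report = filter_loops([loop], [iv("chr1", 11999, 13000)])
        assert kept == []
        assert report.blacklist_removed == 1

    def test_adjacent_blacklist_does_not_remove(self):
        loop = mk_loop("chr1", 10000, "chr1", 50000)
        kept, _ = filter_loops([loop], [iv("chr1", 12000, 13000)])
        assert kept == [loop]

    def test_report_accounting(self):
        loops = [
            mk_loop("chr1", 10000, "chr1", 50000, pets=1),
            mk_loop("chr1", 10000, "chr1", 60000, pets=2),
            mk_loop("chr1", 100000, "chr1", 150000, pets=4),  # blacklisted
            mk_loop("chr1", 200000, "chr1", 260000, pets=4),
            mk_loop("chr1", 300000, "chr1", 360000, pets=9),
        ]
        kept, report = filter_loops(loops, [iv("chr1", 100500, 101000)])
        assert (report.input, report.pet_removed, report.blacklist_removed, report.kept) == (5, 2, 1, 2)
        assert len(kept) == 2

    def test_pet_failure_counted_before_blacklist(self):
        # a loop failing both filters counts only under the PET reason
        loop = mk_loop("chr1", 10000, "chr1", 50000, pets=1)
        _, report = filter_loops([loop], [iv("chr1", 10000, 12000)])
        assert report.pet_removed == 1
        assert report.blacklist_removed == 0

    def test_empty_inputs(self):
        kept, report = filter_loops([], [])
        assert kept == [] and report.input == 0 and report.kept == 0


class TestClassifyLoop:
    def test_trans(self):
        assert classify_loop(mk_loop("chr1", 1000, "chr2", 1000)) is LoopClass.TRANS

    def test_short_span_dropped(self):
        # midpoints 1,500 and 3,500: span 2,000 <= 5,000
        loop = Loop(iv("chr1", 500, 2500), iv("chr1", 2500, 4500), 5)
        assert classify_loop(loop) is LoopClass.DROPPED_SHORT

    def test_span_exactly_min_is_dropped(self):
        loop = Loop(iv("chr1", 0, 2000), iv("chr1", 5000, 7000), 5)
        assert loop.span == 5000
        assert classify_loop(loop) is LoopClass.DROPPED_SHORT

    def test_span_just_above_min_is_normal(self):
        loop = Loop(iv("chr1", 0, 2000), iv("chr1", 5001, 7001), 5)
        assert classify_loop(loop) is LoopClass.NORMAL

    def test_span_exactly_two_mb_is_abnormal_cis(self):
        # midpoints 100,000 and 2,100,000
        loop = Loop(iv("chr1", 99000, 101000), iv("chr1", 2099000, 2101000), 5)
        assert loop.span == 2_000_000
        assert classify_loop(loop) is LoopClass.ABNORMAL_CIS

    def test_span_just_below_two_mb_is_normal(self):
        loop = Loop(iv("chr1", 99000, 101000), iv("chr1", 2098999, 2100999), 5)
        assert classify_loop(loop) is LoopClass.NORMAL

    def test_independent_of_pets(self):
        a, b = iv("chr1", 0, 2000), iv("chr1", 500000, 502000)
        assert classify_loop(Loop(a, b, 3)) == classify_loop(Loop(a, b, 300))

    @given(
        s1=st.integers(0, 3_000_000), s2=st.integers(0, 3_000_000),
        w1=st.integers(100, 3000), w2=st.integers(100, 3000),
    )
    def test_conservation_and_symmetry(self, s1, s2, w1, w2):
        loop = Loop(iv("chr1", s1, s1 + w1), iv("chr1", s2, s2 + w2), 5)
        swapped = Loop(iv("chr1", s2, s2 + w2), iv("chr1", s1, s1 + w1), 5)
        cls = classify_loop(loop)
        assert cls is classify_loop(swapped)
        assert cls in set(LoopClass)


class TestAnnotateAnchors:
    tss = [
        TSSRecord("GENE1", "chr1", 100_000),
        TSSRecord("GENE2", "chr1", 103_000),
        TSSRecord("GENE3", "chr2", 100_000),
    ]

    def test_promoter_window(self):
        loop = Loop(iv("chr1", 99_000, 101_000), iv("chr1", 500_000, 501_000), 5)
        ann = annotate_anchors([loop], [TSSRecord("GENE1", "chr1", 100_000)])
        assert ann[loop.anchor1].genes == {"GENE1"}
        assert ann[loop.anchor2].role == "ENHANCER"

    def test_multi_gene_promoter(self):
        anchor = iv("chr1", 99_000, 102_000)
        loop = Loop(anchor, iv("chr1", 500_000, 501_000), 5)
        ann = annotate_anchors([loop], self.tss)
        assert ann[anchor].genes == {"GENE1", "GENE2"}

    def test_window_is_half_open(self):
        # window [tss-2500, tss+2500); anchor starting at tss+2500 misses
        loop = Loop(iv("chr1", 102_500, 104_000), iv("chr1", 500_000, 501_000), 5)
        ann = annotate_anchors([loop], [TSSRecord("GENE1", "chr1", 100_000)])
        assert not ann[loop.anchor1].is_promoter
        # one bp earlier overlaps
        loop2 = Loop(iv("chr1", 102_499, 104_000), iv("chr1", 500_000, 501_000), 5)
        ann2 = annotate_anchors([loop2], [TSSRecord("GENE1", "chr1", 100_000)])
        assert ann2[loop2.anchor1].genes == {"GENE1"}

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            annotate_anchors([], [])

    @given(st.lists(st.integers(0, 200_000), min_size=1, max_size=30),
           st.integers(0, 200_000), st.integers(500, 5000))
    def test_matches_brute_force(self, tss_positions, anchor_start, anchor_width):
        tss = [TSSRecord(f"G{i}", "chr1", pos) for i, pos in enumerate(tss_positions)]
        anchor = iv("chr1", anchor_start, anchor_start + anchor_width)
        loop = Loop(anchor, iv("chr9", 1, 2), 5)
        ann = annotate_anchors([loop], tss, promoter_halfwidth=2500)
        expected = {
            t.gene for t in tss
            if max(t.tss - 2500, 0) < anchor.end and anchor.start < t.tss + 2500
        }
        assert ann[anchor].genes == expected


class TestExtractEpLoops:
    tss = [TSSRecord("GENE1", "chr1", 100_000), TSSRecord("GENE2", "chr1", 103_000),
           TSSRecord("GENE3", "chr1", 900_000)]

    def _annotate(self, loops):
        return annotate_anchors(loops, self.tss)

    def test_single_promoter_yields_ep_loop(self):
        # anchor ends before GENE2's window [100,500, 105,500)
        loop = Loop(iv("chr1", 99_000, 100_400), iv("chr1", 500_000, 501_000), 7)
        ep, counts = extract_ep_loops([loop], self._annotate([loop]))
        assert len(ep) == 1
        assert ep[0].gene == "GENE1" and ep[0].pets == 7
        assert ep[0].loop_class is LoopClass.NORMAL

    def test_promoter_promoter_excluded(self):
        loop = Loop(iv("chr1", 99_000, 100_500), iv("chr1", 899_000, 901_000), 7)
        ep, counts = extract_ep_loops([loop], self._annotate([loop]))
        assert ep == [] and counts.promoter_promoter == 1

    def test_enhancer_enhancer_excluded(self):
        loop = Loop(iv("chr1", 400_000, 402_000), iv("chr1", 500_000, 501_000), 7)
        ep, counts = extract_ep_loops([loop], self._annotate([loop]))
        assert ep == [] and counts.enhancer_enhancer == 1

    def test_multi_gene_fanout(self):
        loop = Loop(iv("chr1", 99_000, 102_000), iv("chr1", 500_000, 501_000), 4)
        ep, _ = extract_ep_loops([loop], self._annotate([loop]))
        assert sorted(lp.gene for lp in ep) == ["GENE1", "GENE2"]
        assert all(lp.pets == 4 for lp in ep)

    def test_three_loop_fixture_matches_hand_enumeration(self):
        loops = [
            Loop(iv("chr1", 99_000, 102_000), iv("chr1", 500_000, 501_000), 4),  # 2 genes
            Loop(iv("chr1", 899_000, 901_000), iv("chr2", 500_000, 501_000), 6),  # GENE3, trans
            Loop(iv("chr1", 400_000, 402_000), iv("chr1", 500_000, 501_000), 3),  # E-E
        ]
        ep, counts = extract_ep_loops(loops, self._annotate(loops))
        assert sorted((lp.gene, lp.pets, lp.loop_class) for lp in ep) == [
            ("GENE1", 4, LoopClass.NORMAL),
            ("GENE2", 4, LoopClass.NORMAL),
            ("GENE3", 6, LoopClass.TRANS),
        ]
        assert counts.enhancer_enhancer == 1 and counts.ep_loops == 2

    def test_class_inherited_from_loop(self):
        loop = Loop(iv("chr1", 99_000, 101_000), iv("chr1", 5_000_000, 5_002_000), 7)
        ep, _ = extract_ep_loops([loop], self._annotate([loop]))
        assert ep[0].loop_class is LoopClass.ABNORMAL_CIS

    def test_dropped_short_rejected(self):
        loop = Loop(iv("chr1", 99_000, 101_000), iv("chr1", 100_500, 102_500), 7)
        with pytest.raises(ValueError, match="DROPPED_SHORT"):
            extract_ep_loops([loop], self._annotate([loop]))

    def test_unannotated_anchor_is_internal_error(self):
        loop = Loop(iv("chr1", 99_000, 101_000), iv("chr1", 500_000, 501_000), 7)
        with pytest.raises(RuntimeError, match="unannotated"):
            extract_ep_loops([loop], {})

    def test_ep_loop_rejects_dropped_short_class(self):
        with pytest.raises(ValueError):
            EPLoop("G", iv("chr1", 0, 10), iv("chr1", 20, 30), 5, LoopClass.DROPPED_SHORT)


def test_classification_conservation_on_fixture(small_fixture):
    from hapi.io import read_loops

    loops = read_loops(small_fixture.loops_path)
    kept, report = filter_loops(loops, [])
    counts = {cls: 0 for cls in LoopClass}
    for lp in kept:
        counts[classify_loop(lp)] += 1
    assert sum(counts.values()) == len(kept)
    assert report.pet_removed + report.blacklist_removed + report.kept == report.input


def test_anchor_annotation_role_consistency():
    ann = AnchorAnnotation(genes=frozenset({"A"}))
    assert ann.is_promoter and ann.role == "PROMOTER"
    assert AnchorAnnotation().role == "ENHANCER"
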