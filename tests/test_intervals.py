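"""Interval algebra: REF merging, feature windows, peak annotation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldmeth.intervals import (
    ANNOTATION_PRECEDENCE,
    GenomicInterval,
    annotate_peaks,
    derive_feature_windows,
    intersect_counts,
    merge_peak_sets,
)
from coldmeth.io_formats import AnnotationTable


def iv(chrom, s, e):
    return GenomicInterval(chrom, s, e)


class TestGenomicInterval:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_overlap_is_symmetric_and_clipped(self):
        a, b = iv("c", 0, 10), iv("c", 5, 30)
        assert a.overlap(b) == b.overlap(a) == 5
        assert a.overlap(iv("d", 0, 10)) == 0


class TestMergePeakSets:
    def test_one_bp_overlap_merges(self):
        ref = merge_peak_sets({"A": [iv("c", 10, 20)], "B": [iv("c", 19, 25)]})
        assert len(ref) == 1
        assert (ref[0].start, ref[0].end) == (10, 25)
        assert ref[0].source_samples == frozenset({"A", "B"})

    def test_half_open_touch_does_not_merge(self):
        ref = merge_peak_sets({"A": [iv("c", 10, 20)], "B": [iv("c", 20, 30)]})
        assert len(ref) == 2

    def test_identical_sets_collapse_with_all_sources(self):
        sets = {s: [iv("c", 5, 15)] for s in "ABC"}
        ref = merge_peak_sets(sets)
        assert len(ref) == 1
        assert ref[0].source_samples == frozenset("ABC")

    @staticmethod
    def _covered_bases(intervals):
        spans = set()
        for i in intervals:
            spans.update((i.chrom, p) for p in range(i.start, i.end))
        return spans

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["c1", "c2"]),
                st.integers(0, 300),
                st.integers(1, 40),
                st.sampled_from(["s1", "s2", "s3"]),
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_merge_conserves_bases_and_is_idempotent(self, data):
        sets: dict = {}
        for chrom, start, length, sample in data:
            sets.setdefault(sample, []).append(iv(chrom, start, start + length))
        ref = merge_peak_sets(sets)
        # base conservation against the brute-force union of all inputs
        union = self._covered_bases(i for ivs in sets.values() for i in ivs)
        assert self._covered_bases(p.interval for p in ref) == union
        # disjoint and sorted by construction; re-merging changes nothing
        again = merge_peak_sets({"ref": [p.interval for p in ref]})
        assert [(p.chrom, p.start, p.end) for p in again] == [
            (p.chrom, p.start, p.end) for p in ref
        ]
        # order invariance over input set naming
        renamed = merge_peak_sets({f"z{k}": v for k, v in sets.items()})
        assert [(p.start, p.end) for p in renamed] == [(p.start, p.end) for p in ref]


def _annotation(transcripts, exons, repeats=None):
    cols = ["transcript_id", "gene_id", "chrom", "start", "end", "strand",
            "cds_start", "cds_end"]
    tdf = pd.DataFrame(transcripts, columns=cols)
    edf = pd.DataFrame(exons, columns=["transcript_id", "chrom", "start", "end"])
    kwargs = {}
    if repeats is not None:
        kwargs["repeats"] = pd.DataFrame(
            repeats, columns=["chrom", "start", "end", "repeat_class"]
        )
    return AnnotationTable(transcripts=tdf, exons=edf, **kwargs)


class TestFeatureWindows:
    def test_plus_strand_window_arithmetic(self):
        ann = _annotation(
            [("t1", "g1", "c", 5000, 8000, "+", 5000, 8000)],
            [("t1", "c", 5000, 5600), ("t1", "c", 7000, 8000)],
        )
        w = derive_feature_windows(ann, {"c": 20000})
        get = lambda cls: [(x.start, x.end) for x in w.windows[cls]]
        assert get("promoter_up3k") == [(2000, 5000)]
        assert get("downstream5k") == [(8000, 13000)]
        assert get("tss1k") == [(4000, 6000)]
        assert get("intron") == [(5600, 7000)]
        assert get("whole_gene") == [(5000, 8000)]

    def test_minus_strand_mirrors(self):
        ann = _annotation(
            [("t1", "g1", "c", 5000, 8000, "-", 5000, 8000)],
            [("t1", "c", 5000, 8000)],
        )
        w = derive_feature_windows(ann, {"c": 20000})
        assert [(x.start, x.end) for x in w.windows["promoter_up3k"]] == [(8000, 11000)]
        assert [(x.start, x.end) for x in w.windows["downstream5k"]] == [(0, 5000)]

    def test_clipping_at_chromosome_bounds(self):
        ann = _annotation(
            [("t1", "g1", "c", 1000, 2000, "+", 1000, 2000)],
            [("t1", "c", 1000, 2000)],
        )
        w = derive_feature_windows(ann, {"c": 2500})
        assert [(x.start, x.end) for x in w.windows["promoter_up3k"]] == [(0, 1000)]
        assert [(x.start, x.end) for x in w.windows["downstream5k"]] == [(2000, 2500)]

    def test_unstranded_transcript_rejected(self):
        ann = _annotation(
            [("t1", "g1", "c", 100, 200, "+", 100, 200)], [("t1", "c", 100, 200)]
        )
        ann.transcripts.loc[0, "strand"] = "."
        with pytest.raises(ValueError, match="strand"):
            derive_feature_windows(ann, {"c": 1000})


def _brute_force_labels(ref, windows):
    """Oracle: enumerate every window overlap per peak, apply precedence."""
    src = {
        "promoter": "promoter_up3k", "exon": "exon",
        "intron": "intron", "downstream": "downstream5k",
    }
    out = {}
    for peak in ref:
        label = "intergenic"
        for cand in ANNOTATION_PRECEDENCE:
            hits = [
                w for w in windows.windows.get(src[cand], [])
                if w.chrom == peak.chrom and w.start < peak.end and w.end > peak.start
            ]
            if hits:
                label = cand
                break
        out[peak.peak_id] = label
    return out


class TestAnnotatePeaks:
    def test_promoter_precedence_over_intron(self):
        # gene A at [10000,12000)+, gene B at [8000,9500)+ so A's promoter
        # [7000,10000) overlaps B's body
        ann = _annotation(
            [
                ("tA", "gA", "c", 10000, 12000, "+", 10000, 12000),
                ("tB", "gB", "c", 8000, 9500, "+", 8000, 9500),
            ],
            [
                ("tA", "c", 10000, 10100), ("tA", "c", 11900, 12000),
                ("tB", "c", 8000, 8100), ("tB", "c", 9400, 9500),
            ],
        )
        w = derive_feature_windows(ann, {"c": 50000})
        ref = merge_peak_sets({"s": [iv("c", 8500, 8700)]})
        # peak lies in gene B's intron AND gene A's promoter window
        assert annotate_peaks(ref, w) == {"peak_00001": "promoter"}

    def test_unannotated_chromosome_is_intergenic(self):
        ann = _annotation(
            [("t1", "g1", "c", 100, 200, "+", 100, 200)], [("t1", "c", 100, 200)]
        )
        w = derive_feature_windows(ann, {"c": 1000, "other": 1000})
        ref = merge_peak_sets({"s": [iv("other", 10, 50)]})
        assert annotate_peaks(ref, w)["peak_00001"] == "intergenic"

    def test_matches_brute_force_oracle_on_synthetic_study(self, small_study):
        ref = merge_peak_sets(
            {s: calls[:100] for s, calls in small_study.peak_calls.items()}
        )
        windows = derive_feature_windows(
            small_study.genome.annotation, small_study.genome.chrom_sizes
        )
        assert annotate_peaks(ref, windows) == _brute_force_labels(ref, windows)


class TestIntersectCounts:
    def test_count_once_per_peak(self):
        ref = merge_peak_sets({"s": [iv("c", 0, 100)]})
        regions = [iv("c", 10, 20), iv("c", 30, 40), iv("c", 50, 60)]
        assert intersect_counts(ref, regions) == 1

    def test_disjoint_sets_give_zero(self):
        ref = merge_peak_sets({"s": [iv("c", 0, 10)]})
        assert intersect_counts(ref, [iv("c", 50, 60)]) == 0

    def test_single_bp_overlap_counts(self):
        ref = merge_peak_sets({"s": [iv("c", 10, 20)]})
        assert intersect_counts(ref, [iv("c", 19, 25)]) == 1
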