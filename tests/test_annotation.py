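"""Depletion-rank means, TFBS thresholding, interval overlap, proportion tests."""

import numpy as np
import pandas as pd
import pytest

from mprakit.annotation import (
    AnnotationError,
    dr_mean,
    filter_tfbs,
    overlap_flank,
    proportion_test,
    summarize_overlaps,
)
from mprakit.library_design import VariantRecord


def _variant(pos, vid="v1", chrom="chr1"):
    return VariantRecord(vid, chrom, pos, "A", "C")


def _windows(starts, drs, chrom="chr1", width=500):
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": [s + width for s in starts], "dr": drs}
    )


class TestDrMean:
    def test_constant_track(self):
        track = _windows([0, 50, 100], [0.4, 0.4, 0.4])
        assert dr_mean(_variant(pos=120), track) == pytest.approx(0.4)

    def test_arithmetic_mean_of_covering_windows(self):
        track = _windows([0, 50, 100, 600], [0.1, 0.2, 0.3, 0.9])
        assert dr_mean(_variant(pos=120), track) == pytest.approx(0.2)

    def test_order_invariance(self):
        track = _windows([100, 0, 50], [0.3, 0.1, 0.2])
        assert dr_mean(_variant(pos=120), track) == pytest.approx(0.2)

    def test_uncovered_variant_is_nan(self):
        track = _windows([1000], [0.5])
        assert np.isnan(dr_mean(_variant(pos=120), track))

    def test_tiled_track_covers_about_ten_windows(self):
        # 50 bp steps across a 500 bp window: an interior base sits in 10 windows
        track = _windows(list(range(0, 2000, 50)), [0.5] * 40)
        p0 = 999
        covering = track[(track.start <= p0) & (p0 < track.end)]
        assert len(covering) == 10

    def test_malformed_window_rejected(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [400], "dr": [0.5]})
        with pytest.raises(AnnotationError, match="malformed"):
            dr_mean(_variant(pos=120), track)


class TestFilterTfbs:
    def _scores(self, pairs):
        return pd.DataFrame(
            [(v, f"TF{i}", s) for i, (v, s) in enumerate(pairs)],
            columns=["variant_id", "tf", "score"],
        )

    def test_cutoff_inclusive_and_signed(self):
        kept, flags = filter_tfbs(self._scores([("v1", -0.85), ("v2", 0.8), ("v3", 0.79)]))
        assert kept["direction"].tolist() == ["disrupt", "create"]
        assert flags.to_dict() == {"v1": True, "v2": True, "v3": False}

    def test_all_subthreshold_flags_false(self):
        _, flags = filter_tfbs(self._scores([("v1", 0.5), ("v1", -0.3)]))
        assert not flags["v1"]

    def test_score_out_of_range_rejected(self):
        with pytest.raises(AnnotationError):
            filter_tfbs(self._scores([("v1", 1.2)]))


class TestOverlapFlank:
    def _intervals(self, spans, track="dnase"):
        return pd.DataFrame(
            [("chr1", s, e, track) for s, e in spans],
            columns=["chrom", "start", "end", "track"],
        )

    def test_boundary_inclusion(self):
        # footprint of pos 1000 with flank 100 is [899, 1100): reaches 1099
        hits = overlap_flank([_variant(1000)], self._intervals([(1090, 1200)]))
        assert hits.loc["v1", "dnase"]

    def test_boundary_exclusion(self):
        hits = overlap_flank([_variant(1000)], self._intervals([(1101, 1200)]))
        assert not hits.loc["v1", "dnase"]

    def test_zero_flank_requires_containment(self):
        intervals = self._intervals([(999, 1000)])
        assert overlap_flank([_variant(1000)], intervals, flank=0).loc["v1", "dnase"]
        assert not overlap_flank([_variant(1001)], intervals, flank=0).loc["v1", "dnase"]

    def test_negative_flank_rejected(self):
        with pytest.raises(AnnotationError):
            overlap_flank([_variant(1000)], self._intervals([(0, 10)]), flank=-1)

    def test_multiple_tracks_columns(self):
        intervals = pd.concat(
            [self._intervals([(900, 950)], "dnase"), self._intervals([(5000, 5100)], "h3k27ac")]
        )
        hits = overlap_flank([_variant(1000)], intervals)
        assert hits.loc["v1", "dnase"] and not hits.loc["v1", "h3k27ac"]


class TestProportionTest:
    def test_three_group_uncorrected(self):
        res = proportion_test([1, 22, 856], [27, 91, 5094])
        assert res.df == 2
        assert res.pvalue == pytest.approx(0.033, abs=5e-4)

    def test_two_group_continuity_corrected(self):
        res = proportion_test([23, 856], [118, 5094])
        assert res.df == 1
        assert res.pvalue == pytest.approx(0.518, abs=5e-4)

    def test_equal_proportions_large_n(self):
        res = proportion_test([500, 500], [5000, 5000])
        assert res.pvalue > 0.95

    def test_uncorrected_2x2_equals_squared_z(self):
        from statsmodels.stats.proportion import proportions_ztest

        counts, sizes = [40, 70], [200, 260]
        res = proportion_test(counts, sizes, correction=False)
        z, _ = proportions_ztest(counts, sizes)
        assert res.statistic == pytest.approx(z**2, abs=1e-10)

    def test_count_exceeding_size_rejected(self):
        with pytest.raises(AnnotationError):
            proportion_test([5, 2], [4, 10])


class TestSummarizeOverlaps:
    GROUPS = {
        "allele_specific": {"promoter": 1, "enhancer": 16},
        "general": {"promoter": 22, "enhancer": 46},
        "background": {"promoter": 856, "enhancer": 2765},
    }
    SIZES = {"allele_specific": 27, "general": 91, "background": 5094}

    def test_percentages_match_published_cells(self):
        out = summarize_overlaps(self.GROUPS, self.SIZES)
        assert out.loc["allele_specific", "enhancer_pct"] == 59.26
        assert out.loc["general", "enhancer_pct"] == 50.55
        assert out.loc["background", "promoter_pct"] == 16.80

    def test_merged_layout_pools_enhancer_groups(self):
        out = summarize_overlaps(self.GROUPS, self.SIZES)
        merged = proportion_test([1 + 22, 856], [27 + 91, 5094])
        assert out.loc["p_merged", "promoter_pct"] == pytest.approx(merged.pvalue)

    def test_empty_class_is_zero(self):
        groups = {"a": {"mark": 0}, "b": {"mark": 3}}
        out = summarize_overlaps(groups, {"a": 10, "b": 10})
        assert out.loc["a", "mark_count"] == 0
        assert out.loc["a", "mark_pct"] == 0.0
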