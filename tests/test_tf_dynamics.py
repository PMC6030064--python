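"""Peak overlap rules, Oct4 fates, nearest genes, ATAC filtering and tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromfate.core_io import FragmentSet, GenomicInterval, TssAnnotation
from chromfate.synthetic_data import SimulationConfig, simulate_atac, simulate_tf_peaks
from chromfate.tf_dynamics import (
    PeakSet,
    classify_oct4_fate,
    compare_peak_sets,
    filter_fragments_by_size,
    interval_gap,
    nearest_tss,
    signal_in_peaks_test,
)


class TestIntervalGap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (150, 250), 0),
            ((100, 200), (260, 300), 60),
            ((100, 200), (301, 400), 101),
        ],
    )
    def test_examples(self, a, b, expected):
        ia = GenomicInterval("chr1", *a)
        ib = GenomicInterval("chr1", *b)
        assert interval_gap(ia, ib) == expected

    def test_cross_chromosome_is_infinite(self):
        a = GenomicInterval("chr1", 0, 10)
        b = GenomicInterval("chr2", 0, 10)
        assert math.isinf(interval_gap(a, b))

    @given(
        st.integers(0, 10_000), st.integers(1, 500),
        st.integers(0, 10_000), st.integers(1, 500),
    )
    def test_symmetry_and_overlap(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        assert interval_gap(a, b) == interval_gap(b, a)
        assert (interval_gap(a, b) == 0) == a.overlaps(b)


class TestComparePeakSets:
    def _ps(self, cond, triples):
        return PeakSet("Oct4", cond, [GenomicInterval(*t) for t in triples])

    def test_identical_sets_all_shared(self):
        a = self._ps("WT", [("chr1", 0, 100), ("chr1", 500, 600)])
        cmp = compare_peak_sets(a, a)
        assert len(cmp.a_specific) == 0 and len(cmp.b_specific) == 0
        assert len(cmp.a_shared) == 2

    def test_gap_50_is_shared(self):
        a = self._ps("WT", [("chr1", 0, 100)])
        b = self._ps("KO", [("chr1", 150, 250)])
        cmp = compare_peak_sets(a, b, tol=100)
        assert len(cmp.a_shared) == 1 and len(cmp.b_shared) == 1

    def test_gap_101_is_specific(self):
        a = self._ps("WT", [("chr1", 0, 100)])
        b = self._ps("KO", [("chr1", 201, 300)])
        cmp = compare_peak_sets(a, b, tol=100)
        assert len(cmp.a_specific) == 1 and len(cmp.b_specific) == 1

    def test_each_peak_classified_once(self, small_cfg):
        peaksets, _ = simulate_tf_peaks(small_cfg, dict(small_cfg.chromosomes))
        a, b = peaksets[("Oct4", "WT")], peaksets[("Oct4", "KO")]
        cmp = compare_peak_sets(a, b)
        assert len(cmp.a_specific) + len(cmp.a_shared) == len(a)
        assert len(cmp.b_specific) + len(cmp.b_shared) == len(b)


class TestClassifyOct4Fate:
    def _iv(self, s, e):
        return GenomicInterval("chr1", s, e)

    def test_both_factors_within_100(self):
        oct4 = PeakSet("Oct4", "WT", [self._iv(1_000, 1_400)])
        sox2 = PeakSet("Sox2", "KO", [self._iv(1_500, 1_900)])
        nanog = PeakSet("Nanog", "KO", [self._iv(500, 900)])
        calls, fractions = classify_oct4_fate(oct4, sox2, nanog)
        assert calls[0].fate == "Sox2_Nanog_replacement"
        assert fractions["Sox2_Nanog_replacement"] == 1.0

    def test_boundary_gap_100_counts_101_does_not(self):
        oct4 = PeakSet("Oct4", "WT", [self._iv(1_000, 1_400), self._iv(9_000, 9_400)])
        sox2 = PeakSet(
            "Sox2", "KO", [self._iv(1_500, 1_900), self._iv(9_501, 9_901)]
        )
        nanog = PeakSet("Nanog", "KO", [])
        calls, _ = classify_oct4_fate(oct4, sox2, nanog)
        assert [c.fate for c in calls] == ["Sox2_replacement", "loss"]

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            calls, fractions = classify_oct4_fate(
                PeakSet("Oct4", "WT", []),
                PeakSet("Sox2", "KO", []),
                PeakSet("Nanog", "KO", []),
            )
        assert calls == [] and fractions.sum() == 0.0

    def test_planted_fractions_recovered_exactly(self, small_cfg):
        peaksets, truth = simulate_tf_peaks(small_cfg, dict(small_cfg.chromosomes))
        oct4 = compare_peak_sets(peaksets[("Oct4", "WT")], peaksets[("Oct4", "KO")])
        sox2 = compare_peak_sets(peaksets[("Sox2", "WT")], peaksets[("Sox2", "KO")])
        nanog = compare_peak_sets(peaksets[("Nanog", "WT")], peaksets[("Nanog", "KO")])
        calls, fractions = classify_oct4_fate(
            oct4.a_specific, sox2.b_specific, nanog.b_specific
        )
        called = pd.Series({c.peak.name: c.fate for c in calls})
        planted = truth.set_index("peak_name")["fate"]
        assert (called.reindex(planted.index) == planted).all()
        assert fractions.sum() == pytest.approx(1.0)


class TestNearestTss:
    def test_closest_wins(self, tiny_tss):
        # peak midpoint 11,000: geneA TSS at 10,000 (d=1,000) beats geneB (d=29,000)
        assert nearest_tss(GenomicInterval("chr1", 10_800, 11_200), tiny_tss) == "geneA"

    def test_tie_breaks_lexicographically(self):
        tss = TssAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["geneB", "geneA"],
                    "chrom": ["chr1", "chr1"],
                    "strand": ["+", "+"],
                    "tss": [4_000, 6_000],
                }
            )
        )
        assert nearest_tss(GenomicInterval("chr1", 4_900, 5_100), tss) == "geneA"

    def test_no_tss_on_chromosome(self, tiny_tss):
        assert nearest_tss(GenomicInterval("chr9", 0, 100), tiny_tss) == "NA"


class TestFragmentSizeFilter:
    def test_strict_threshold(self, make_fragset):
        frags = make_fragset(
            "atac", [("chr1", 0, 149), ("chr1", 0, 150), ("chr1", 0, 151)]
        )
        kept = filter_fragments_by_size(frags, 150)
        assert kept.library_size == 1
        assert (kept.df["end"] - kept.df["start"]).tolist() == [149]

    def test_empty_input(self):
        frags = FragmentSet.from_intervals("atac", [])
        assert filter_fragments_by_size(frags).library_size == 0

    def test_retains_planted_sub150_fraction(self, small_cfg):
        wt, _, _, truth = simulate_atac(small_cfg, dict(small_cfg.chromosomes))
        sizes = (wt.df["end"] - wt.df["start"]).to_numpy()
        kept = filter_fragments_by_size(wt, 150)
        # the filter keeps exactly the sub-150 set ...
        assert kept.library_size == int((sizes < 150).sum())
        # ... and that set's share matches the configured mixture (3 binomial SE)
        f = truth["sub150_fraction"]
        se = np.sqrt(f * (1 - f) / len(sizes))
        assert abs((sizes < 150).mean() - f) < 3 * se


class TestSignalInPeaksTest:
    def test_identical_libraries_degenerate(self, make_fragset):
        frags = make_fragset("x", [("chr1", 1_000, 1_100), ("chr1", 5_000, 5_100)])
        peaks = PeakSet(
            "Oct4", "WT",
            [GenomicInterval("chr1", 900, 1_300), GenomicInterval("chr1", 4_900, 5_300)],
        )
        with pytest.warns(UserWarning, match="2 peaks"):
            table, summary = signal_in_peaks_test(frags, frags, peaks)
        assert np.allclose(table["log2_ratio"], 0.0)
        assert summary["p_value"] == 1.0 and summary["zero_variance"] == 1.0

    def test_planted_depletion_detected(self, small_cfg):
        wt, ko, peaks, truth = simulate_atac(small_cfg, dict(small_cfg.chromosomes))
        table, summary = signal_in_peaks_test(
            filter_fragments_by_size(wt), filter_fragments_by_size(ko), peaks
        )
        assert summary["mean_log2_ratio"] == pytest.approx(
            truth["expected_log2_ratio"], abs=0.25
        )
        assert summary["p_value"] < 1e-6

    def test_too_few_peaks_errors(self, make_fragset):
        frags = make_fragset("x", [("chr1", 0, 100)])
        with pytest.raises(ValueError):
            signal_in_peaks_test(
                frags, frags, PeakSet("p", "c", [GenomicInterval("chr1", 0, 200)])
            )
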