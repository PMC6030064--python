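"""Poisson test, BH step-up, window testing and region calling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromfate.core_io import CountPair, GenomicInterval, TssAnnotation
from chromfate.enrichment import (
    annotate_regions,
    bh_adjust,
    call_differential_windows,
    poisson_upper_pvalue,
)
from chromfate.enrichment import test_window as run_window_test
from chromfate.synthetic_data import simulate_differential_regions


def brute_force_upper_tail(k: int, lam: float) -> float:
    """Independent oracle: P(X >= k) = 1 - sum_{j < k} e^-lam lam^j / j!."""
    terms = [math.exp(-lam + j * math.log(lam) - math.lgamma(j + 1)) for j in range(k)]
    return 1.0 - math.fsum(terms)


def stepup_oracle(p):
    """Literal BH step-up, written independently of the implementation."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = running_min
    return q


class TestPoissonUpperPvalue:
    def test_zero_count_is_one(self):
        assert poisson_upper_pvalue(0, 3.7) == 1.0

    @pytest.mark.parametrize(
        "k,lam,expected",
        [(10, 2.0, 4.6498075017248694e-05), (5, 5.0, 0.5595067149347875)],
    )
    def test_reference_values(self, k, lam, expected):
        # frozen from the brute-force pmf summation oracle
        assert poisson_upper_pvalue(k, lam) == pytest.approx(expected, rel=1e-9)
        assert brute_force_upper_tail(k, lam) == pytest.approx(expected, rel=1e-9)

    def test_oracle_equivalence_grid(self):
        for lam in (0.5, 1, 2, 5, 10, 20):
            for k in range(51):
                assert abs(
                    poisson_upper_pvalue(k, lam) - brute_force_upper_tail(k, lam)
                ) < 1e-10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_upper_pvalue(3, 0.0)
        with pytest.raises(ValueError):
            poisson_upper_pvalue(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_upper_pvalue(2.5, 2.0)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_independent_stepup(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), stepup_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=50)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_properties(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-15)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTestWindow:
    def _pair(self, chip, inp, chip_lib=1_000_000, input_lib=1_000_000):
        return CountPair(
            GenomicInterval("chr1", 0, 10_000), chip, inp, chip_lib, input_lib
        )

    def test_strong_enrichment(self):
        wt = run_window_test(self._pair(100, 20))
        # lam ~ 20.5 against an observed 100: overwhelming evidence
        assert wt.p_enrich < 1e-15
        assert wt.log2_ratio > 1

    def test_equal_counts_ratio_zero(self):
        wt = run_window_test(self._pair(50, 50))
        assert wt.log2_ratio == pytest.approx(0.0)

    def test_symmetry_of_directions(self):
        a = run_window_test(self._pair(80, 20))
        b = run_window_test(self._pair(20, 80))
        assert a.p_enrich == pytest.approx(b.p_deplete)
        assert a.log2_ratio == pytest.approx(-b.log2_ratio)


class TestCallDifferentialWindows:
    def test_planted_region_recovered(self, small_cfg):
        sizes = dict(small_cfg.region_chromosomes)
        chip, inp, planted = simulate_differential_regions(small_cfg, sizes)
        calls = call_differential_windows(chip, inp, sizes)
        assert len(calls.enriched) == len(planted)
        for called, true in zip(
            sorted(calls.enriched, key=lambda r: r.start),
            sorted(planted, key=lambda r: r.start),
        ):
            # boundaries within one step of the planted region
            assert abs(called.start - true.start) <= calls.step_bp
            assert abs(called.end - true.end) <= calls.step_bp
        assert calls.depleted == []

    def test_identical_libraries_no_calls(self, small_cfg):
        sizes = dict(small_cfg.region_chromosomes)
        chip, _, _ = simulate_differential_regions(small_cfg, sizes)
        calls = call_differential_windows(chip, chip, sizes)
        assert calls.enriched == [] and calls.depleted == []

    def test_swap_exchanges_directions(self, small_cfg):
        sizes = dict(small_cfg.region_chromosomes)
        chip, inp, _ = simulate_differential_regions(small_cfg, sizes)
        fwd = call_differential_windows(chip, inp, sizes)
        rev = call_differential_windows(inp, chip, sizes)
        key = lambda rs: [(r.chrom, r.start, r.end) for r in rs]
        assert key(fwd.enriched) == key(rev.depleted)
        assert key(fwd.depleted) == key(rev.enriched)

    def test_invalid_parameters(self, small_cfg):
        sizes = dict(small_cfg.region_chromosomes)
        chip, inp, _ = simulate_differential_regions(small_cfg, sizes)
        with pytest.raises(ValueError):
            call_differential_windows(chip, inp, sizes, window_bp=0)
        with pytest.raises(ValueError):
            call_differential_windows(chip, inp, sizes, step_bp=-1)


class TestAnnotateRegions:
    @pytest.fixture
    def annotation(self, tiny_tss):
        genes = [
            GenomicInterval("chr1", 10_000, 20_000, "+", "geneA"),
            GenomicInterval("chr1", 30_000, 40_001, "-", "geneB"),
        ]
        return genes, tiny_tss

    def test_gene_body(self, annotation):
        genes, tss = annotation
        labels, _ = annotate_regions(
            [GenomicInterval("chr1", 15_000, 16_000)], genes, tss
        )
        assert labels == ["gene_body"]

    def test_promoter_precedence_over_gene_body(self, annotation):
        genes, tss = annotation
        labels, _ = annotate_regions(
            [GenomicInterval("chr1", 9_000, 15_000)], genes, tss
        )
        assert labels == ["promoter"]

    def test_intergenic_on_empty_chromosome(self, annotation):
        genes, tss = annotation
        labels, summary = annotate_regions(
            [GenomicInterval("chr9", 0, 1_000)], genes, tss
        )
        assert labels == ["intergenic"]
        assert summary["fraction"].sum() == pytest.approx(1.0)
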