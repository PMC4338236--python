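import numpy as np
import pytest

from hapsweep.haplodata import HaplotypeMatrix, RecombinationMap
from hapsweep.hapstats import HomozygosityStats
from hapsweep.scan import (
    WindowResult,
    calibrate_fdr,
    call_peaks,
    expected_overlap,
    peak_edges,
    scan_chromosome,
    sliding_windows,
)


class TestSlidingWindows:
    def test_hand_enumeration(self):
        assert sliding_windows(500, 400, 50) == [(0, 400), (50, 450), (100, 500)]

    def test_exactly_one_window(self):
        assert sliding_windows(400, 400, 50) == [(0, 400)]

    def test_insufficient_snps(self):
        assert sliding_windows(399, 400, 50) == []

    def test_bad_args(self):
        with pytest.raises(ValueError):
            sliding_windows(100, 0, 50)


def _matrix(n_haps, n_snps, rng, monomorphic=False):
    if monomorphic:
        alleles = np.zeros((n_haps, n_snps), dtype=np.int8)
        alleles[0] = 1  # keep each column segregating but haplotypes identical
    else:
        alleles = rng.integers(0, 2, size=(n_haps, n_snps)).astype(np.int8)
    return HaplotypeMatrix("chrS", np.arange(1, n_snps + 1) * 20, alleles)


class TestScanChromosome:
    def test_unmasked_windows(self, rng):
        m = _matrix(20, 500, rng)
        rmap = RecombinationMap.constant("chrS", 20_000, 1e-6)
        res = scan_chromosome(m, rmap, rng)
        assert len(res) == 3
        assert all(not r.masked for r in res)
        assert [r.snp_start for r in res] == [0, 50, 100]
        # center = SNP at index start + 200
        assert res[1].center_position == m.positions[50 + 200]

    def test_low_recombination_masks_all(self, rng):
        m = _matrix(20, 500, rng)
        rmap = RecombinationMap.constant("chrS", 20_000, 1e-7)
        res = scan_chromosome(m, rmap, rng)
        assert all(r.masked for r in res)

    def test_monomorphic_haplotypes_give_h12_one(self, rng):
        m = _matrix(20, 500, rng, monomorphic=True)
        rmap = RecombinationMap.constant("chrS", 20_000, 1e-6)
        res = scan_chromosome(m, rmap, rng)
        assert all(r.h12 == pytest.approx(1.0) for r in res)

    def test_too_few_snps_errors(self, rng):
        m = _matrix(10, 399, rng)
        rmap = RecombinationMap.constant("chrS", 20_000, 1e-6)
        with pytest.raises(ValueError, match="400"):
            scan_chromosome(m, rmap, rng)


class TestCalibrateFdr:
    def test_order_statistic(self):
        cal = calibrate_fdr(np.arange(20, 0, -1), n_genome_windows=2)
        assert cal.h12_critical == 11

    def test_ten_equal_values(self):
        cal = calibrate_fdr(np.full(10, 0.25), n_genome_windows=1)
        assert cal.h12_critical == 0.25

    def test_matches_full_sort_oracle(self, rng):
        values = rng.beta(1, 30, size=1000)
        cal = calibrate_fdr(values, n_genome_windows=100)
        assert cal.h12_critical == sorted(values, reverse=True)[9]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            calibrate_fdr(np.arange(9), 1)


def _results(h12s, masked=None):
    masked = masked or [False] * len(h12s)
    out = []
    for i, (h, m) in enumerate(zip(h12s, masked)):
        stats = HomozygosityStats(h1=h, h12=h, h123=h, h2=0.0, h2_h1=0.1, k=5)
        out.append(
            WindowResult(
                window_index=i,
                snp_start=i * 50,
                snp_end=i * 50 + 400,
                center_position=1000 + 100 * i,
                stats=stats,
                rho=1e-6,
                masked=m,
            )
        )
    return out


class TestCallPeaks:
    def test_hand_grouping(self):
        res = _results([0.010, 0.020, 0.030, 0.020, 0.010, 0.005, 0.020])
        peaks = call_peaks(res, 0.015)
        assert len(peaks) == 2
        assert (peaks[0].first_window, peaks[0].last_window) == (1, 3)
        assert peaks[0].h12 == pytest.approx(0.030)
        assert (peaks[1].first_window, peaks[1].last_window) == (6, 6)
        assert peaks[1].h12 == pytest.approx(0.020)

    def test_all_below_threshold(self):
        assert call_peaks(_results([0.01, 0.011]), 0.5) == []

    def test_masked_flanks_single_window_peak(self):
        res = _results([0.03, 0.03, 0.03], masked=[True, False, True])
        peaks = call_peaks(res, 0.015)
        assert len(peaks) == 1
        assert peaks[0].n_windows == 1
        assert peaks[0].rep_window == 1

    def test_masked_window_splits_run(self):
        res = _results([0.03, 0.04, 0.05], masked=[False, True, False])
        peaks = call_peaks(res, 0.015)
        assert [p.rep_window for p in peaks] == [2, 0]

    def test_peak_union_is_all_qualifying_windows(self, rng):
        h12s = rng.beta(1, 20, size=60)
        masked = list(rng.random(60) < 0.2)
        res = _results(list(h12s), masked)
        thr = float(np.median(h12s))
        peaks = call_peaks(res, thr)
        covered = set()
        for p in peaks:
            covered |= set(range(p.first_window, p.last_window + 1))
        qualifying = {
            r.window_index for r in res if not r.masked and r.h12 > thr
        }
        assert covered == qualifying

    def test_raising_threshold_shrinks_peaks(self, rng):
        h12s = list(rng.beta(1, 20, size=60))
        res = _results(h12s)
        low = call_peaks(res, 0.02)
        high = call_peaks(res, 0.05)
        n_low = sum(p.n_windows for p in low)
        n_high = sum(p.n_windows for p in high)
        assert n_high <= n_low

    def test_edge_coordinates(self, rng):
        m = _matrix(10, 500, rng)
        res = _results([0.03, 0.03, 0.01])
        peak = call_peaks(res, 0.02)[0]
        filled = peak_edges(peak, m, res)
        assert filled.edge_start == int(m.positions[0])
        assert filled.edge_end == int(m.positions[449])


def test_neutral_h12_null_invariant_to_locus_length():
    """The central-400-SNP H12 null depends only on window-scale genealogy,
    so short simulated loci can stand in for long ones at equal per-bp rates
    (KS at alpha = 0.005, reduced replicates)."""
    from scipy.stats import ks_2samp

    from hapsweep.scan import neutral_h12_null
    from hapsweep.sweepsim import Demography, SweepModel

    def null(length, seed):
        model = SweepModel(
            demography=Demography(ne=1e6), locus_length=length, mu=1e-9,
            rho_cm_per_bp=5e-7, mode="neutral", sample_size=145,
        )
        return neutral_h12_null(model, n_sims=250, seed=seed)

    assert ks_2samp(null(100_000, 41), null(30_000, 42)).pvalue > 0.005


class TestExpectedOverlap:
    def test_degenerate_full_overlap(self):
        frac, _, _ = expected_overlap(100, 100, 100, 1, 1)
        assert frac == pytest.approx(1.0)

    def test_linearity_in_enrichment_size(self):
        f1, _, _ = expected_overlap(1e6, 2e6, 1e8, 10, 10)
        f2, _, _ = expected_overlap(1e6, 1e6, 1e8, 10, 10)
        assert f1 == pytest.approx(2 * f2)

    def test_zero_sizes_error(self):
        with pytest.raises(ValueError):
            expected_overlap(0, 1, 1, 1, 1)
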