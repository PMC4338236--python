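"""Sliding-window H12 genome scan, FDR calibration, and peak calling.

The scan slides windows of a fixed number of SNPs (default 400, stepped by
50) along a chromosome, computes the haplotype-homozygosity statistics in
each, masks windows in low-recombination regions, and groups above-threshold
windows into peaks.  The significance threshold H12_o is calibrated to a
1-per-genome false-discovery rate: simulate ten times as many neutral loci
as there are analysis windows in the genome and take the 10th highest H12.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hapsweep.haplodata import HaplotypeMatrix, RecombinationMap
from hapsweep.hapstats import HomozygosityStats, window_stats
from hapsweep.sweepsim import SweepModel, simulate_neutral_alleles

__all__ = [
    "WindowResult",
    "Peak",
    "FdrCalibration",
    "sliding_windows",
    "scan_chromosome",
    "calibrate_fdr",
    "call_peaks",
    "expected_overlap",
    "neutral_h12_null",
    "central_window_h12",
    "windows_to_frame",
    "peaks_to_frame",
]

WINDOW_SIZE = 400
WINDOW_STEP = 50
RHO_MIN = 5e-7  # cM/bp


@dataclass(frozen=True)
class WindowResult:
    """Statistics of one analysis window."""

    window_index: int
    snp_start: int  # half-open SNP index range [snp_start, snp_end)
    snp_end: int
    center_position: int
    stats: HomozygosityStats
    rho: float  # cM/bp; NaN when unknown
    masked: bool

    @property
    def h12(self) -> float:
        return self.stats.h12


@dataclass(frozen=True)
class Peak:
    """A maximal run of consecutive unmasked windows above threshold."""

    chrom: str
    first_window: int
    last_window: int
    edge_start: int
    edge_end: int
    rep_window: int
    rep_center: int
    h12: float
    h2_h1: float
    n_windows: int


@dataclass(frozen=True)
class FdrCalibration:
    """A 1-per-genome FDR critical value from neutral simulations."""

    demography: str
    rho: float
    n_simulations: int
    h12_critical: float


def sliding_windows(
    n_snps: int, size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> list[tuple[int, int]]:
    """Half-open SNP index ranges [i, i+size) stepped by ``step``.

    Trailing partial windows are not emitted; fewer than ``size`` SNPs gives
    an empty list.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    return [(i, i + size) for i in range(0, n_snps - size + 1, step)]


def scan_chromosome(
    matrix: HaplotypeMatrix,
    recmap: RecombinationMap,
    rng: np.random.Generator,
    rho_min: float = RHO_MIN,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[WindowResult]:
    """Score every analysis window of one chromosome.

    Windows whose center falls where the recombination rate is below
    ``rho_min`` (or unknown) are flagged ``masked``; they carry statistics
    but are excluded from peak calling.
    """
    if matrix.n_snps < size:
        raise ValueError(
            f"chromosome has {matrix.n_snps} SNPs; at least {size} are "
            f"required for one analysis window"
        )
    results = []
    for w, (start, end) in enumerate(sliding_windows(matrix.n_snps, size, step)):
        stats = window_stats(matrix.alleles, start, size, rng)
        center = int(matrix.positions[start + size // 2])
        rho = recmap.rate_at(matrix.chrom, center)
        masked = not (rho >= rho_min)  # NaN fails the comparison -> masked
        results.append(
            WindowResult(
                window_index=w,
                snp_start=start,
                snp_end=end,
                center_position=center,
                stats=stats,
                rho=rho,
                masked=masked,
            )
        )
    return results


def calibrate_fdr(
    neutral_h12_values: np.ndarray,
    n_genome_windows: int,
    demography: str = "constant",
    rho: float = RHO_MIN,
) -> FdrCalibration:
    """1-per-genome FDR critical value: the 10th highest neutral H12.

    The intended list length is ten times the number of genome analysis
    windows, so that the threshold is exceeded by about one neutral window
    per genome scan.
    """
    values = np.asarray(neutral_h12_values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need >= 10 neutral H12 values, got {values.size}")
    crit = float(np.sort(values)[-10])
    return FdrCalibration(
        demography=demography,
        rho=rho,
        n_simulations=int(values.size),
        h12_critical=crit,
    )


def call_peaks(results: list[WindowResult], h12_o: float, chrom: str = "") -> list[Peak]:
    """Group consecutive unmasked above-threshold windows into peaks.

    Peaks are maximal runs of adjacent (50-SNP-step) unmasked windows with
    H12 > ``h12_o``; each is represented by its highest-H12 member window.
    Output is sorted by representative H12, descending.  A masked window
    terminates a run.
    """
    peaks: list[Peak] = []
    run: list[WindowResult] = []

    def flush(run: list[WindowResult]) -> None:
        if not run:
            return
        rep = max(run, key=lambda r: r.h12)
        peaks.append(
            Peak(
                chrom=chrom,
                first_window=run[0].window_index,
                last_window=run[-1].window_index,
                edge_start=0,
                edge_end=0,
                rep_window=rep.window_index,
                rep_center=rep.center_position,
                h12=rep.h12,
                h2_h1=rep.stats.h2_h1,
                n_windows=len(run),
            )
        )

    ordered = sorted(results, key=lambda r: r.window_index)
    for res in ordered:
        if not res.masked and res.h12 > h12_o:
            if run and res.window_index != run[-1].window_index + 1:
                flush(run)
                run = []
            run.append(res)
        else:
            flush(run)
            run = []
    flush(run)
    peaks.sort(key=lambda p: -p.h12)
    return peaks


def peak_edges(peak: Peak, matrix: HaplotypeMatrix, results: list[WindowResult]) -> Peak:
    """Fill in bp edge coordinates: first SNP of the first member window
    through last SNP of the last member window."""
    by_index = {r.window_index: r for r in results}
    first = by_index[peak.first_window]
    last = by_index[peak.last_window]
    return replace(
        peak,
        edge_start=int(matrix.positions[first.snp_start]),
        edge_end=int(matrix.positions[last.snp_end - 1]),
    )


def expected_overlap(
    peak_bp: float,
    enrich_bp: float,
    genome_bp: float,
    n_peaks: int,
    n_enrich: int,
) -> tuple[float, float, float]:
    """Chance overlap between two sets of candidate regions.

    Returns ``(overlap_fraction, expected_peaks, expected_windows)`` where
    ``overlap_fraction`` is the product of the two genome fractions and the
    expectations assume candidates are spread uniformly over the genome.
    """
    if min(peak_bp, enrich_bp, genome_bp) <= 0:
        raise ValueError("all region sizes must be positive")
    overlap_fraction = (peak_bp / genome_bp) * (enrich_bp / genome_bp)
    expected_peaks = n_peaks * (overlap_fraction * genome_bp) / peak_bp
    expected_windows = n_enrich * (overlap_fraction * genome_bp) / enrich_bp
    return overlap_fraction, expected_peaks, expected_windows


def central_window_h12(
    matrix: HaplotypeMatrix, rng: np.random.Generator, size: int = WINDOW_SIZE
) -> float:
    """H12 of the central ``size`` SNPs, the convention for simulated loci."""
    if matrix.n_snps < size:
        raise ValueError(f"{matrix.n_snps} SNPs < window of {size}")
    start = (matrix.n_snps - size) // 2
    return window_stats(matrix.alleles, start, size, rng).h12


def neutral_h12_null(
    model: SweepModel,
    n_sims: int,
    seed: int,
    size: int = WINDOW_SIZE,
) -> np.ndarray:
    """H12 null distribution from neutral simulations of ``model``.

    Each replicate is a neutral coalescent sample; H12 is computed on the
    central ``size`` SNPs.  Replicates with fewer than ``size`` SNPs are
    discarded and redrawn.
    """
    if model.mode != "neutral":
        raise ValueError("calibration model must be neutral")
    rng = np.random.default_rng(seed)
    out = np.empty(n_sims)
    reps = simulate_neutral_alleles(model, n_sims, int(rng.integers(1, 2**31 - 1)),
                                    min_snps=size)
    for i, alleles in enumerate(reps):
        start = (alleles.shape[1] - size) // 2
        out[i] = window_stats(alleles, start, size, rng).h12
    return out


def windows_to_frame(results: list[WindowResult], chrom: str) -> pd.DataFrame:
    """Scan results as a tidy table (one row per window)."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "center_pos": [r.center_position for r in results],
            "snp_start": [r.snp_start for r in results],
            "snp_end": [r.snp_end for r in results],
            "h1": [r.stats.h1 for r in results],
            "h12": [r.stats.h12 for r in results],
            "h123": [r.stats.h123 for r in results],
            "h2": [r.stats.h2 for r in results],
            "h2_h1": [r.stats.h2_h1 for r in results],
            "rho": [r.rho for r in results],
            "masked": [r.masked for r in results],
        }
    )


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    """Peaks as a BED-like table."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "edge_start": [p.edge_start for p in peaks],
            "edge_end": [p.edge_end for p in peaks],
            "rep_center": [p.rep_center for p in peaks],
            "rep_h12": [p.h12 for p in peaks],
            "rep_h2_h1": [p.h2_h1 for p in peaks],
            "n_windows": [p.n_windows for p in peaks],
        }
    )
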