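"""Pairwise linkage-disequilibrium decay profiles.

LD between SNP pairs is measured with the R^2 statistic on the haplotypes
non-missing at both sites; a pair needs at least four complete haplotypes
and both sites polymorphic in that subset.  Pairs are formed within sliding
10-kb windows (stepped by 50 bp) between the first minor-allele-frequency
passing SNP of each window and every other passing SNP, and pooled R^2
values are binned by distance: 20-bp bins up to 300 bp, 150-bp bins beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hapsweep.haplodata import MISSING, HaplotypeMatrix

__all__ = ["LdProfile", "r_squared", "ld_decay", "MIN_COMPLETE_PAIRS"]

MIN_COMPLETE_PAIRS = 4


@dataclass
class LdProfile:
    """Mean R^2 by distance bin: (start, end, mean R^2, pair count)."""

    bins: list[tuple[int, int, float, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bins, columns=["dist_start", "dist_end", "mean_r2", "n_pairs"]
        )

    @property
    def empty(self) -> bool:
        return not self.bins


def r_squared(col_a: np.ndarray, col_b: np.ndarray) -> float | None:
    """R^2 between two allele columns, or ``None`` when excluded.

    Computed on haplotypes non-missing at both sites; excluded (``None``)
    when fewer than :data:`MIN_COMPLETE_PAIRS` complete haplotypes remain or
    either site is monomorphic in the complete subset.
    """
    a = np.asarray(col_a, dtype=np.int8)
    b = np.asarray(col_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("allele columns must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    if int(ok.sum()) < MIN_COMPLETE_PAIRS:
        return None
    a, b = a[ok].astype(float), b[ok].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _maf_pass(matrix: HaplotypeMatrix, lo: float, hi: float) -> np.ndarray:
    """Mask of SNPs whose allele-1 frequency (on non-missing haplotypes)
    lies in [lo, hi], bounds inclusive."""
    alleles = matrix.alleles
    present = alleles != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            present.sum(axis=0) > 0,
            (alleles == 1).sum(axis=0) / present.sum(axis=0),
            -1.0,
        )
    return (freq >= lo) & (freq <= hi)


def ld_decay(
    matrix: HaplotypeMatrix,
    window: int = 10_000,
    step: int = 50,
    maf: tuple[float, float] = (0.05, 0.95),
    short_bin: int = 20,
    short_limit: int = 300,
    long_bin: int = 150,
) -> LdProfile:
    """LD decay profile of one chromosome.

    For each window anchor position the pairs are (first MAF-passing SNP in
    the window, every later MAF-passing SNP in the window); identical pairs
    arising in successive overlapping windows are counted once.  Pooled R^2
    values are averaged within the distance-bin scheme.
    """
    passing = np.flatnonzero(_maf_pass(matrix, *maf))
    if passing.size < 2:
        return LdProfile(bins=[])
    pos = matrix.positions[passing]
    pairs: set[tuple[int, int]] = set()
    first_pos = int(matrix.positions[0])
    last_pos = int(matrix.positions[-1])
    for wstart in range(first_pos, last_pos + 1, step):
        in_win = np.flatnonzero((pos >= wstart) & (pos < wstart + window))
        if in_win.size < 2:
            continue
        anchor = in_win[0]
        for other in in_win[1:]:
            pairs.add((int(passing[anchor]), int(passing[other])))

    dists: list[int] = []
    r2s: list[float] = []
    for i, j in pairs:
        r2 = r_squared(matrix.alleles[:, i], matrix.alleles[:, j])
        if r2 is None:
            continue
        dists.append(abs(int(matrix.positions[j]) - int(matrix.positions[i])))
        r2s.append(r2)
    if not r2s:
        return LdProfile(bins=[])

    dist_arr = np.array(dists)
    r2_arr = np.array(r2s)
    edges = list(range(0, short_limit + 1, short_bin))
    e = short_limit
    while e < window:
        e += long_bin
        edges.append(min(e, window + 1))
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist_arr >= lo) & (dist_arr < hi)
        if sel.any():
            bins.append((lo, hi, float(r2_arr[sel].mean()), int(sel.sum())))
    return LdProfile(bins=bins)
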