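"""Haplotype clustering within a window and the H1/H12/H123/H2 statistics.

Within a fixed-SNP analysis window, haplotypes are grouped by exact sequence
identity; haplotypes carrying missing data join a group when they match its
representative at every genotyped site, with ties broken uniformly at
random.  From the descending group-frequency spectrum p_1 >= p_2 >= ... the
homozygosity statistics are

    H1   = sum_i p_i^2
    H12  = (p_1 + p_2)^2 + sum_{i>2} p_i^2  = H1 + 2 p_1 p_2
    H123 = (p_1 + p_2 + p_3)^2 + sum_{i>3} p_i^2
    H2   = H1 - p_1^2
    H2/H1

H12 detects both hard and soft sweeps; H2/H1 rises with the softness of a
sweep and is interpretable where H12 is already high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hapsweep.haplodata import MISSING

__all__ = [
    "HaplotypeSpectrum",
    "HomozygosityStats",
    "cluster_window",
    "homozygosity",
    "window_stats",
]


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Descending haplotype-group sizes within one window."""

    counts: np.ndarray  # descending, each >= 1
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.size == 0 or self.n <= 0:
            raise ValueError("spectrum must contain at least one haplotype")
        if counts.min() < 1:
            raise ValueError("cluster sizes must be >= 1")
        if np.any(np.diff(counts) > 0):
            raise ValueError("cluster sizes must be sorted descending")
        if counts.sum() != self.n:
            raise ValueError(f"cluster sizes sum to {counts.sum()}, n = {self.n}")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def k(self) -> int:
        """Number of distinct haplotype groups."""
        return int(self.counts.size)


@dataclass(frozen=True)
class HomozygosityStats:
    h1: float
    h12: float
    h123: float
    h2: float
    h2_h1: float
    k: int


def homozygosity(spectrum: HaplotypeSpectrum) -> HomozygosityStats:
    """Compute H1, H12, H123, H2 and H2/H1 from a frequency spectrum.

    Spectra with fewer than two (three) groups pad the missing p values
    with zero, so a complete hard sweep (k = 1) yields H12 = H123 = 1 and
    H2/H1 = 0.
    """
    p = spectrum.frequencies
    p1 = p[0]
    p2 = p[1] if p.size > 1 else 0.0
    p3 = p[2] if p.size > 2 else 0.0
    h1 = float(np.sum(p**2))
    h12 = h1 + 2.0 * p1 * p2
    h123 = h12 + 2.0 * p3 * (p1 + p2)
    h2 = h1 - p1**2
    return HomozygosityStats(
        h1=h1, h12=h12, h123=h123, h2=h2, h2_h1=h2 / h1, k=spectrum.k
    )


def cluster_window(
    window_alleles: np.ndarray, rng: np.random.Generator
) -> HaplotypeSpectrum:
    """Group the haplotypes of one window by exact identity.

    Complete (N-free) haplotypes are grouped first by exact sequence
    identity.  Haplotypes containing missing data are then processed in
    input-row order: a haplotype joins an existing group when it matches the
    group representative at all sites genotyped in both sequences; when
    several groups match, one is chosen uniformly at random via ``rng``;
    when none match, the haplotype founds a new group and its own sequence
    (missing sites included) becomes the representative.  An all-missing
    haplotype therefore joins a uniformly random existing group.

    The random tie-break makes the result order-dependent under missing
    data; pass a seeded generator for reproducibility.
    """
    window = np.asarray(window_alleles, dtype=np.int8)
    if window.ndim != 2 or window.shape[0] == 0:
        raise ValueError("window must be a non-empty 2-D matrix")
    n = window.shape[0]
    has_n = (window == MISSING).any(axis=1)

    counts: list[int] = []
    reps: list[np.ndarray] = []
    seen: dict[bytes, int] = {}
    for row in window[~has_n]:
        key = row.tobytes()
        idx = seen.get(key)
        if idx is None:
            seen[key] = len(counts)
            counts.append(1)
            reps.append(row)
        else:
            counts[idx] += 1

    if has_n.any():
        rep_mat = (
            np.array(reps, dtype=np.int8)
            if reps
            else np.empty((0, window.shape[1]), dtype=np.int8)
        )
        for row in window[has_n]:
            if rep_mat.shape[0]:
                ok = (
                    (rep_mat == row[None, :])
                    | (row[None, :] == MISSING)
                    | (rep_mat == MISSING)
                ).all(axis=1)
                matches = np.flatnonzero(ok)
            else:
                matches = np.empty(0, dtype=np.int64)
            if matches.size == 0:
                counts.append(1)
                rep_mat = np.vstack([rep_mat, row[None, :]])
            else:
                pick = (
                    int(matches[0])
                    if matches.size == 1
                    else int(rng.choice(matches))
                )
                counts[pick] += 1

    out = np.sort(np.array(counts, dtype=np.int64))[::-1]
    return HaplotypeSpectrum(counts=out, n=n)


def window_stats(
    alleles: np.ndarray,
    start: int,
    size: int,
    rng: np.random.Generator,
) -> HomozygosityStats:
    """Cluster ``alleles[:, start:start+size]`` and compute its statistics."""
    return homozygosity(cluster_window(alleles[:, start : start + size], rng))
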