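"""Unpolarized iHS scan and |iHS| enrichment windows.

For each core SNP, EHH(x) is the probability that two randomly chosen
carriers of an allele are identical at every SNP between the core and x.
iHH integrates EHH over physical distance away from the core in both
directions, truncated where EHH falls below a cutoff (default 0.05).  The
unstandardized score is ln(iHH_major / iHH_minor); without ancestral
polarization the alleles are oriented major/minor, and scores are
standardized to mean 0, variance 1 within minor-allele-frequency bins so
that |iHS| is comparable across frequencies.  Candidate regions are
non-overlapping 100-kb windows ranked by their count of |iHS| > 2 SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hapsweep.haplodata import MISSING, HaplotypeMatrix

__all__ = [
    "IhsResult",
    "EnrichmentWindows",
    "ehh",
    "ihs_scan",
    "enrichment_windows",
]


@dataclass
class IhsResult:
    """Per-SNP iHS values; dropped SNPs carry a reason instead of a score."""

    positions: np.ndarray
    maf: np.ndarray
    ihs_raw: np.ndarray  # NaN where dropped
    ihs_std: np.ndarray  # NaN where dropped
    dropped_reason: np.ndarray  # "" where kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos": self.positions,
                "maf": self.maf,
                "ihs_raw": self.ihs_raw,
                "ihs_std": self.ihs_std,
                "dropped_reason": self.dropped_reason,
            }
        )


@dataclass
class EnrichmentWindows:
    """Non-overlapping windows tiling the chromosome from position 1."""

    starts: np.ndarray  # window start positions (1-based)
    counts: np.ndarray  # SNPs with |standardized iHS| > threshold
    top: np.ndarray  # top-decile flag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start": self.starts, "count": self.counts, "top": self.top}
        )


def ehh(
    matrix: HaplotypeMatrix,
    core: int,
    allele: int,
    direction: int,
) -> tuple[np.ndarray, np.ndarray] | None:
    """EHH curve for carriers of ``allele`` at SNP index ``core``.

    ``direction`` is +1 (rightward) or -1 (leftward).  Returns
    ``(positions, ehh_values)`` starting at the core (where EHH = 1),
    or ``None`` when fewer than two carriers remain.  Haplotypes with
    missing data are dropped as the extension reaches them.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    carriers = np.flatnonzero(matrix.alleles[:, core] == allele)
    if carriers.size < 2:
        return None
    if direction == 1:
        cols = range(core, matrix.n_snps)
    else:
        cols = range(core, -1, -1)

    active = carriers
    groups = np.zeros(active.size, dtype=np.int64)
    out_pos: list[int] = []
    out_ehh: list[float] = []
    for j in cols:
        col = matrix.alleles[active, j]
        keep = col != MISSING
        if not keep.all():
            active = active[keep]
            groups = groups[keep]
            col = col[keep]
            if active.size < 2:
                break
        # refine the identity partition by this column
        key = groups * 2 + col
        _, groups = np.unique(key, return_inverse=True)
        sizes = np.bincount(groups)
        n = active.size
        out_pos.append(int(matrix.positions[j]))
        out_ehh.append(float((sizes * (sizes - 1)).sum() / (n * (n - 1))))
    if not out_pos:
        return None
    return np.array(out_pos), np.array(out_ehh)


def _ihh(curve: tuple[np.ndarray, np.ndarray] | None, cutoff: float) -> float | None:
    """Integrate an EHH curve over bp until it falls below ``cutoff``.

    Integration is trapezoidal between successive SNPs and includes the
    segment down to the first sub-cutoff point.  Returns ``None`` when the
    curve never decays below the cutoff before the end of the data ("edge")
    or when there is no curve at all.
    """
    if curve is None:
        return None
    pos, vals = curve
    total = 0.0
    for i in range(1, pos.size):
        step = abs(int(pos[i]) - int(pos[i - 1]))
        total += 0.5 * (vals[i] + vals[i - 1]) * step
        if vals[i] < cutoff:
            return total
    return None  # ran off the chromosome end before decaying


def ihs_scan(
    matrix: HaplotypeMatrix,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    std_bin: float = 0.1,
) -> IhsResult:
    """iHS at every SNP with minor-allele frequency >= ``maf_min``.

    Scores are standardized within MAF bins of width ``std_bin`` (mean 0,
    sd 1 per bin).  Dropped SNPs carry one of the reasons ``maf``,
    ``carriers`` (an allele has < 2 carriers), ``edge`` (EHH did not decay
    below the cutoff before the chromosome end) or ``bin`` (too few SNPs in
    the MAF bin to standardize).
    """
    n_snps = matrix.n_snps
    present = matrix.alleles != MISSING
    with np.errstate(invalid="ignore"):
        freq1 = np.where(
            present.sum(axis=0) > 0,
            (matrix.alleles == 1).sum(axis=0) / present.sum(axis=0),
            0.0,
        )
    maf = np.minimum(freq1, 1 - freq1)
    raw = np.full(n_snps, np.nan)
    reason = np.array([""] * n_snps, dtype=object)

    for j in range(n_snps):
        if maf[j] < maf_min:
            reason[j] = "maf"
            continue
        # orient major/minor; frequency ties put allele 1 on the minor side
        minor = 1 if freq1[j] <= 0.5 else 0
        major = 1 - minor
        ihh = {}
        dropped = None
        for allele in (major, minor):
            left = _ihh(ehh(matrix, j, allele, -1), ehh_cutoff)
            right = _ihh(ehh(matrix, j, allele, +1), ehh_cutoff)
            if left is None or right is None:
                curve_l = ehh(matrix, j, allele, -1)
                curve_r = ehh(matrix, j, allele, +1)
                dropped = (
                    "carriers" if curve_l is None or curve_r is None else "edge"
                )
                break
            ihh[allele] = left + right
        if dropped:
            reason[j] = dropped
            continue
        if ihh[major] <= 0 or ihh[minor] <= 0:
            reason[j] = "edge"
            continue
        raw[j] = np.log(ihh[major] / ihh[minor])

    std = np.full(n_snps, np.nan)
    ok = np.isfinite(raw)
    bin_idx = np.floor(maf / std_bin).astype(int)
    for b in np.unique(bin_idx[ok]):
        sel = ok & (bin_idx == b)
        if sel.sum() < 2 or raw[sel].std() == 0:
            reason[sel] = "bin"
            continue
        std[sel] = (raw[sel] - raw[sel].mean()) / raw[sel].std()
    return IhsResult(
        positions=matrix.positions.copy(),
        maf=maf,
        ihs_raw=raw,
        ihs_std=std,
        dropped_reason=reason.astype(str),
    )


def enrichment_windows(
    result: IhsResult,
    window: int = 100_000,
    top_fraction: float = 0.10,
    threshold: float = 2.0,
) -> EnrichmentWindows:
    """Count |standardized iHS| > ``threshold`` SNPs in tiling windows.

    Windows tile from position 1; the top ``top_fraction`` of windows by
    count are flagged, ties broken in favor of the leftmost windows.
    """
    if result.positions.size == 0:
        return EnrichmentWindows(
            starts=np.empty(0, int), counts=np.empty(0, int), top=np.empty(0, bool)
        )
    last = int(result.positions.max())
    starts = np.arange(1, last + 1, window)
    counts = np.zeros(starts.size, dtype=int)
    hits = result.positions[np.abs(result.ihs_std) > threshold]
    if hits.size:
        idx = (hits - 1) // window
        for i in idx:
            counts[int(i)] += 1
    n_top = int(np.ceil(top_fraction * starts.size))
    # sort by (-count, start): highest counts first, leftmost wins ties
    order = np.lexsort((starts, -counts))
    top = np.zeros(starts.size, dtype=bool)
    top[order[:n_top]] = True
    return EnrichmentWindows(starts=starts, counts=counts, top=top)
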