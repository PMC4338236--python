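"""Haplotype matrices, recombination maps, and the file formats that carry them.

Conventions used throughout the package:

* Genomic positions are 1-based integers, as in VCF.
* Interval semantics are half-open ``[start, end)``.
* Alleles are coded ``0``/``1``; missing data (``N``) is coded ``-1``.
  Heterozygous calls in effectively-haploid (inbred line) data are treated
  as missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "RATE_UNKNOWN",
    "DGRP_EXCLUDED_LINES",
    "HaplotypeMatrix",
    "RecombinationMap",
    "exclude_samples",
    "read_vcf",
    "read_ms",
    "read_tsv",
    "write_tsv",
]

#: DGRP inbred lines excluded by the quality filter (the 10% of the 162
#: sequenced lines with the most residual heterozygosity); removing them
#: from the 162 reference genomes leaves the 145-strain analysis panel.
DGRP_EXCLUDED_LINES = (
    "49", "85", "101", "109", "136", "153", "237", "309", "317",
    "325", "338", "352", "377", "386", "426", "563", "802",
)

#: Allele code for missing data ("N").
MISSING = -1

#: Sentinel returned by :meth:`RecombinationMap.rate_at` for positions not
#: covered by any interval.  It is NaN so that every comparison against a
#: rate threshold fails, which callers must treat as "masked".
RATE_UNKNOWN = float("nan")


class MsFormatError(ValueError):
    """Raised when an ms/msms-style block cannot be parsed."""


@dataclass
class HaplotypeMatrix:
    """Phased haplotype alleles at SNPs along one chromosome.

    Parameters
    ----------
    chrom :
        Chromosome label.
    positions :
        Strictly increasing 1-based bp coordinates, one per SNP column.
    alleles :
        ``(n_haplotypes, n_snps)`` int8 matrix over {0, 1, -1}; -1 is
        missing data.
    sample_ids :
        One label per haplotype row.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError(
                f"{self.alleles.shape[1]} allele columns != "
                f"{self.positions.size} positions"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1, or -1 (missing)")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]
        if len(self.sample_ids) != self.alleles.shape[0]:
            raise ValueError("sample_ids length != number of haplotype rows")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]


@dataclass
class RecombinationMap:
    """Per-interval recombination rates in cM/bp.

    Intervals are ``(chrom, start, end, rate)`` with 1-based start and
    half-open ``[start, end)`` semantics, non-overlapping per chromosome.
    """

    intervals: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, rate in self.intervals:
            if rate < 0:
                raise ValueError(f"negative recombination rate {rate}")
            if end <= start:
                raise ValueError(f"empty interval [{start}, {end})")
            per.setdefault(str(chrom), []).append((int(start), int(end), float(rate)))
        for chrom, ivs in per.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            rates = np.array([r for _, _, r in ivs], dtype=float)
            self._by_chrom[chrom] = (starts, ends, rates)

    @classmethod
    def from_bed(cls, path: str) -> "RecombinationMap":
        """Read a BED-like TSV: chrom, start (1-based), end, rate (cM/bp)."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, rate = line.split("\t")[:4]
                ivs.append((chrom, int(start), int(end), float(rate)))
        return cls(ivs)

    def rate_at(self, chrom: str, position: int) -> float:
        """Rate of the interval covering ``position``, or :data:`RATE_UNKNOWN`.

        The NaN sentinel fails every ``rate >= threshold`` comparison, so
        uncovered positions automatically fail any rate filter.
        """
        if position < 1:
            raise ValueError("positions are 1-based; got %r" % position)
        entry = self._by_chrom.get(str(chrom))
        if entry is None:
            return RATE_UNKNOWN
        starts, ends, rates = entry
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < ends[i]:
            return float(rates[i])
        return RATE_UNKNOWN

    @staticmethod
    def constant(chrom: str, length: int, rate: float) -> "RecombinationMap":
        """A single-interval map covering ``[1, length+1)`` at ``rate``."""
        return RecombinationMap([(chrom, 1, length + 1, rate)])


def exclude_samples(
    matrix: HaplotypeMatrix, exclude_ids: tuple[str, ...] | list[str]
) -> HaplotypeMatrix:
    """Drop haplotype rows whose sample id is in ``exclude_ids``."""
    excluded = set(exclude_ids)
    keep = [i for i, sid in enumerate(matrix.sample_ids) if sid not in excluded]
    if not keep:
        raise ValueError("all samples excluded")
    return HaplotypeMatrix(
        matrix.chrom,
        matrix.positions,
        matrix.alleles[keep],
        [matrix.sample_ids[i] for i in keep],
    )


def read_vcf(path: str, region: str | None = None, haploid: bool = False) -> HaplotypeMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Multiallelic records and non-SNPs are skipped.  Diploid samples are
    split into two haplotype rows when the genotype is phased; unphased
    heterozygotes become missing on both rows.  With ``haploid=True`` each
    sample contributes a single row and any heterozygous call is treated as
    missing, which is the right reading for inbred-line panels.

    Parameters
    ----------
    region :
        Optional chromosome label; only records on it are kept.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    chrom_seen: str | None = None
    last_pos = -1
    for var in vcf:
        if region is not None and var.CHROM != region:
            continue
        if not var.is_snp or len(var.ALT) != 1:
            continue
        if chrom_seen is None:
            chrom_seen = var.CHROM
        elif var.CHROM != chrom_seen:
            raise ValueError(
                f"multiple chromosomes in VCF ({chrom_seen!r}, {var.CHROM!r}); "
                "pass region= to select one"
            )
        if var.POS <= last_pos:
            continue  # duplicate or unsorted record
        col = _vcf_column(var.genotypes, haploid)
        positions.append(var.POS)
        columns.append(col)
        last_pos = var.POS
    if not columns:
        raise ValueError(f"no biallelic SNPs found in {path!r} (region={region!r})")
    alleles = np.stack(columns, axis=1)
    if haploid:
        ids = samples
    else:
        ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
        if alleles.shape[0] == len(samples):  # all-haploid GT fields
            ids = samples
    return HaplotypeMatrix(chrom_seen or "", np.array(positions), alleles, ids)


def _vcf_column(genotypes: list, haploid: bool) -> np.ndarray:
    out: list[int] = []
    for g in genotypes:
        *calls, phased = g
        calls = [MISSING if a < 0 else int(a) for a in calls]
        if len(calls) == 1:
            out.append(calls[0])
            continue
        if haploid:
            out.append(calls[0] if calls[0] == calls[1] else MISSING)
        else:
            if calls[0] != calls[1] and not phased:
                out.extend([MISSING, MISSING])
            else:
                out.extend(calls)
    return np.array(out, dtype=np.int8)


def _fractions_to_bp(fractions: np.ndarray, locus_length: int) -> np.ndarray:
    """Map ms unit-interval positions to distinct integer bp in [1, L]."""
    bp = np.rint(np.asarray(fractions, dtype=float) * locus_length).astype(np.int64)
    bp = np.clip(bp, 1, locus_length)
    if bp.size:
        # rounding can create ties; bump forward to keep strict increase
        # (bp[i] >= bp[i-1] + 1 <=> bp[i] - i non-decreasing)
        idx = np.arange(bp.size)
        bp = np.maximum.accumulate(bp - idx) + idx
    return bp


def read_ms(path: str | io.TextIOBase, locus_length: int, n_expected: int) -> list[HaplotypeMatrix]:
    """Parse ms/msms-style text output into one matrix per replicate.

    Fractional positions are mapped to integer bp in ``[1, locus_length]``
    (ties after rounding are bumped upward to keep positions strictly
    increasing).  Replicate order is preserved.
    """
    if isinstance(path, (str, bytes)):
        with open(path) as fh:
            lines = fh.read().splitlines()
    else:
        lines = path.read().splitlines()
    reps: list[HaplotypeMatrix] = []
    i = 0
    rep_index = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        rep_index += 1
        i += 1
        try:
            while not lines[i].strip():
                i += 1
            seg_line = lines[i].strip()
            if not seg_line.startswith("segsites:"):
                raise MsFormatError(f"expected 'segsites:' got {seg_line!r}")
            segsites = int(seg_line.split(":", 1)[1])
            i += 1
            if segsites == 0:
                reps.append(
                    HaplotypeMatrix(
                        f"rep{rep_index}",
                        np.empty(0, dtype=np.int64),
                        np.empty((n_expected, 0), dtype=np.int8),
                    )
                )
                continue
            pos_line = lines[i].strip()
            if not pos_line.startswith("positions:"):
                raise MsFormatError(f"expected 'positions:' got {pos_line!r}")
            fracs = np.array(pos_line.split(":", 1)[1].split(), dtype=float)
            if fracs.size != segsites:
                raise MsFormatError(
                    f"{fracs.size} positions for segsites: {segsites}"
                )
            i += 1
            rows = []
            for _ in range(n_expected):
                hap = lines[i].strip()
                if len(hap) != segsites or set(hap) - {"0", "1"}:
                    raise MsFormatError(f"bad haplotype row {hap!r}")
                rows.append(np.frombuffer(hap.encode(), dtype=np.uint8) - ord("0"))
                i += 1
            alleles = np.array(rows, dtype=np.int8)
            reps.append(
                HaplotypeMatrix(
                    f"rep{rep_index}",
                    _fractions_to_bp(fracs, locus_length),
                    alleles,
                )
            )
        except (IndexError, ValueError) as err:
            if isinstance(err, MsFormatError):
                raise MsFormatError(f"replicate {rep_index}: {err}") from None
            raise MsFormatError(f"replicate {rep_index}: truncated or malformed block") from err
    return reps


_CHAR = {0: "0", 1: "1", MISSING: "N"}
_CODE = {"0": 0, "1": 1, "N": MISSING}


def write_tsv(matrix: HaplotypeMatrix, path: str) -> None:
    """Write the internal TSV haplotype format.

    Header row: chromosome label then the bp positions; each subsequent row:
    sample id then one 0/1/N character per SNP.
    """
    with open(path, "w") as fh:
        fh.write("\t".join([matrix.chrom] + [str(p) for p in matrix.positions]) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.alleles):
            fh.write("\t".join([sid] + [_CHAR[int(a)] for a in row]) + "\n")


def read_tsv(path: str) -> HaplotypeMatrix:
    """Read the internal TSV haplotype format written by :func:`write_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        chrom, positions = header[0], np.array(header[1:], dtype=np.int64)
        ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            ids.append(fields[0])
            rows.append([_CODE[c] for c in fields[1:]])
    return HaplotypeMatrix(chrom, positions, np.array(rows, dtype=np.int8), ids)
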