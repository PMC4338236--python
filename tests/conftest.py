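import numpy as np
import pytest

from hapsweep.haplodata import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_matrix():
    """Five haplotypes at four SNPs, one missing call."""
    alleles = np.array(
        [
            [0, 1, 0, 1],
            [0, 1, 0, 1],
            [1, 0, 1, 0],
            [0, 1, -1, 1],
            [1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypeMatrix("chrT", [100, 200, 350, 500], alleles)


@pytest.fixture
def ms_text(tmp_path):
    """Hand-written two-replicate ms file (parse checked by hand in tests)."""
    text = """\
ms 2 2 -t 5
1 2 3

//
segsites: 2
positions: 0.25 0.75
01
10

//
segsites: 3
positions: 0.1 0.5 0.9
010
101
"""
    path = tmp_path / "two_reps.ms"
    path.write_text(text)
    return str(path)


@pytest.fixture
def vcf_path(tmp_path):
    """Three diploid samples; 2 phased biallelic SNPs, one triallelic site,
    one indel, and one site with an unphased heterozygote."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=chr2R,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr2R\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
chr2R\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1
chr2R\t300\t.\tA\tT,C\t.\tPASS\t.\tGT\t0|0\t1|2\t0|0
chr2R\t400\t.\tA\tAT\t.\tPASS\t.\tGT\t0|0\t0|1\t0|0
chr2R\t500\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0|0\t1|1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return str(path)
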