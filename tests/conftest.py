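import numpy as np
import pytest

from popdiv.variant_io import MISSING, GenotypeMatrix


def make_matrix(
    dosages,
    pos=None,
    chrom="chr1",
    is_variant=None,
    sample_ids=None,
    **kwargs,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain nested list of dosages."""
    dos = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dos.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    pos = np.asarray(pos, dtype=np.int64)
    if is_variant is None:
        is_variant = np.ones(n_sites, dtype=bool)
    else:
        is_variant = np.asarray(is_variant, dtype=bool)
    if isinstance(chrom, str):
        chrom = np.asarray([chrom] * n_sites, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    ref = np.asarray(["A"] * n_sites, dtype=object)
    alt = np.asarray(["G" if v else "" for v in is_variant], dtype=object)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=chrom,
        pos=pos,
        is_variant=is_variant,
        ref=ref,
        alt=alt,
        dosages=dos,
        **kwargs,
    )


def brute_force_pi(dosages, is_variant=None):
    """Oracle: enumerate every allele pair at every site.

    dosages: (n_samples, n_sites) with MISSING = -1. Each diploid contributes
    two allele copies; mismatches and comparisons are counted by explicit
    enumeration and summed over sites.
    """
    dos = np.asarray(dosages)
    n_samples, n_sites = dos.shape
    total_diff = 0
    total_comp = 0
    for j in range(n_sites):
        alleles = []
        for i in range(n_samples):
            d = dos[i, j]
            if d == MISSING:
                continue
            if d == 0:
                alleles += [0, 0]
            elif d == 1:
                alleles += [0, 1]
            else:
                alleles += [1, 1]
        for a in range(len(alleles)):
            for b in range(a + 1, len(alleles)):
                total_comp += 1
                if alleles[a] != alleles[b]:
                    total_diff += 1
    if total_comp == 0:
        return float("nan")
    return total_diff / total_comp


def brute_force_hudson(dos_a, dos_b):
    """Oracle: per-site Hudson terms from explicit allele counting, ratio of sums."""
    dos_a = np.asarray(dos_a)
    dos_b = np.asarray(dos_b)
    num_sum = 0.0
    den_sum = 0.0
    for j in range(dos_a.shape[1]):
        counts = []
        for dos in (dos_a, dos_b):
            col = dos[:, j]
            called = col[col != MISSING]
            n = 2 * len(called)
            k = int(called.sum())
            counts.append((n, k))
        (n1, k1), (n2, k2) = counts
        if n1 < 2 or n2 < 2:
            continue
        p1 = k1 / n1
        p2 = k2 / n2
        num_sum += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum if den_sum else float("nan")


@pytest.fixture
def toy_vcf(tmp_path):
    """A small hand-written VCF covering variant, invariant, multi-allelic
    and missing-call records."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##INFO=<ID=SOR,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tT\t50\t.\tQD=10;FS=1;MQ=60;SOR=1\tGT\t0/1\t1/1
chr1\t200\t.\tG\t.\t.\t.\t.\tGT:DP:RGQ\t0/0:10:50\t0/0:4:50
chr1\t300\t.\tC\tA,G\t50\t.\tQD=10\tGT\t0/1\t0/2
chr1\t400\t.\tT\tC\t25\t.\tQD=10;FS=1;MQ=60;SOR=1\tGT\t./.\t0/0
chr1\t500\t.\tA\tG\t50\t.\tQD=10;FS=1;MQ=60;SOR=1\tGT\t0/0\t0/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
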