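import numpy as np
import pytest

from chimpanel.maskgen import MosaicParams, simulate_cohort
from chimpanel.vcfio import MISSING, GenotypeMatrix


def make_matrix(calls, positions=None, phased=None, chrom="chr1", sample_ids=None):
    """Build a GenotypeMatrix from a nested list of (a0, a1) call pairs.

    ``calls[i][j]`` is the call of sample i at site j; None means missing.
    """
    n = len(calls)
    s = len(calls[0])
    arr = np.empty((n, s, 2), dtype=np.int8)
    for i, row in enumerate(calls):
        for j, c in enumerate(row):
            arr[i, j] = (MISSING, MISSING) if c is None else c
    if positions is None:
        positions = np.arange(1, s + 1) * 100
    if phased is None:
        ph = arr[:, :, 0] != MISSING
    else:
        ph = np.asarray(phased, dtype=bool)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref_allele=np.array(["A"] * s, dtype=object),
        alt_allele=np.array(["T"] * s, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        calls=arr,
        phased=ph,
    )


def random_matrix(rng, n_samples, n_sites, miss_rate=0.2, spacing=100):
    """Random biallelic matrix with iid missing calls (for property tests)."""
    calls = rng.integers(0, 2, size=(n_samples, n_sites, 2)).astype(np.int8)
    miss = rng.random((n_samples, n_sites)) < miss_rate
    calls[miss] = MISSING
    return GenotypeMatrix(
        chrom="chr1",
        positions=1 + np.arange(n_sites, dtype=np.int64) * spacing,
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["T"] * n_sites, dtype=object),
        sample_ids=np.array([f"S{i}" for i in range(n_samples)], dtype=object),
        calls=calls,
        phased=~miss,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fully observed phased cohort: 60 diploids x 400 sites, block LD."""
    m, founders = simulate_cohort(
        MosaicParams(n_diploids=60, n_sites=400, seed=7)
    )
    return m, founders


@pytest.fixture
def fig_style_vcf(tmp_path):
    """Hand-written 5-sample VCF with scattered missing calls (gaps)."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0/0\t./.\t1|1\t0/1
chr1\t250\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t./.\t0|0\t0/1\t./.
chr1\t400\t.\tG\tA\t.\tPASS\t.\tGT\t0|0\t1|0\t1/1\t./.\t0/0
chr1\t900\t.\tT\tC\t.\tPASS\t.\tGT\t./.\t0/1\t0|1\t1/1\t1|1
"""
    path = tmp_path / "fig.vcf"
    path.write_text(text)
    return path
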