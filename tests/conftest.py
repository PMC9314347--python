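import numpy as np
import pytest

from circsnp.data_io import CircRnaLocus, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n_snps=200, n_loci=30, n_chrom=3, chrom_len=100_000):
    """Random SNPs and loci for oracle comparisons."""
    loci = []
    for i in range(n_loci):
        length = int(rng.integers(50, 5_000))
        start = int(rng.integers(0, chrom_len - length))
        loci.append(
            CircRnaLocus(
                circ_id=f"c{i}",
                chrom=str(int(rng.integers(1, n_chrom + 1))),
                start=start,
                end=start + length,
                n_evidence=int(rng.integers(1, 6)),
            )
        )
    snps = [
        SnpRecord(
            rsid=f"rs{i}",
            chrom=str(int(rng.integers(1, n_chrom + 1))),
            pos=int(rng.integers(1, chrom_len + 1)),
            pvalue=float(rng.uniform(1e-12, 1.0)),
        )
        for i in range(n_snps)
    ]
    return snps, loci


@pytest.fixture
def small_instance(rng):
    return random_instance(rng)
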