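import numpy as np
import pytest

from recessmap import default_family
from recessmap.synthetic_family import GenotypeMatrix


@pytest.fixture(scope="session")
def family42():
    """The default backcross family at seed 42 (shared; treat as read-only)."""
    return default_family(42)


def make_matrix(calls, positions=None, chrom="1", sample_ids=None):
    """Small genotype matrix from a nested list of calls (samples x SNPs)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 1000
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    positions = np.asarray(positions, dtype=np.int64)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=positions,
        snp_ids=np.array([f"snp{i}" for i in range(n_snps)], dtype=object),
        calls=calls,
    )
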