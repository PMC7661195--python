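"""SNP-array quality control: call-rate and minor-allele-frequency filters.

Standard chip QC semantics: a SNP is removed when EITHER criterion fails
(call rate strictly below the threshold, or MAF strictly below the
threshold).  MAF is computed over all genotyped samples pooled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_family import GenotypeMatrix


@dataclass
class QcReport:
    n_input_snps: int
    n_removed_callrate: int
    n_removed_maf: int
    n_retained: int
    call_rate: np.ndarray  # per input SNP, in [0, 1]
    maf: np.ndarray  # per input SNP, in [0, 0.5]; 0 where undefined

    def __post_init__(self):
        if self.n_input_snps != (
            self.n_retained + self.n_removed_callrate + self.n_removed_maf
        ):
            raise ValueError("QC counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_removed_callrate": self.n_removed_callrate,
            "n_removed_maf": self.n_removed_maf,
            "n_retained": self.n_retained,
        }


def compute_snp_stats(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP call rate and minor allele frequency.

    A SNP with zero calls gets call_rate 0 and (undefined) MAF reported as 0.
    """
    if matrix.n_samples < 1 or matrix.n_snps < 1:
        raise ValueError("empty genotype matrix")
    called = matrix.calls >= 0
    call_rate = called.mean(axis=0)
    alt_alleles = np.where(called, matrix.calls, 0).sum(axis=0, dtype=np.int64)
    total_alleles = 2 * called.sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_alt = np.where(total_alleles > 0, alt_alleles / total_alleles, 0.0)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    maf = np.where(total_alleles > 0, maf, 0.0)
    return call_rate, maf


def qc_filter(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with call rate < ``min_call_rate`` or MAF < ``min_maf``.

    Thresholds are exclusive: a SNP exactly at a threshold is retained.
    Sample set and SNP order are preserved.  A SNP failing both criteria is
    counted once, under the call-rate criterion.
    """
    for name, t in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    call_rate, maf = compute_snp_stats(matrix)
    fail_cr = call_rate < min_call_rate
    fail_maf = maf < min_maf
    keep = ~(fail_cr | fail_maf)
    report = QcReport(
        n_input_snps=matrix.n_snps,
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_maf=int((fail_maf & ~fail_cr).sum()),
        n_retained=int(keep.sum()),
        call_rate=call_rate,
        maf=maf,
    )
    return matrix.select_snps(keep), report
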