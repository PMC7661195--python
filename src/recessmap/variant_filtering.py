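"""Small-variant triage: sire-unique heterozygous subtraction and interval restriction.

Under a recessive model with an unaffected carrier sire, the causal allele
must be heterozygous in the sire and absent from a large control cohort.
These are pure row filters over a variant table; an empty result after
restriction to the candidate region is a meaningful outcome — it is what
escalates the analysis to structural variants.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # hom_ref | het | hom_alt

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def select_heterozygous(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep heterozygous records only; order preserved."""
    return [v for v in variants if v.genotype == "het"]


def _cohort_keyset(cohort) -> set[tuple[str, int, str, str]]:
    if isinstance(cohort, pd.DataFrame):
        try:
            return {
                (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
                for r in cohort.itertuples()
            }
        except (AttributeError, ValueError) as exc:
            raise ValueError(f"malformed cohort table: {exc}") from exc
    keys = set()
    for i, site in enumerate(cohort):
        try:
            chrom, pos, ref, alt = site
            keys.add((str(chrom), int(pos), str(ref), str(alt)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed cohort site at line {i + 1}: {site!r}") from exc
    return keys


def subtract_cohort(
    sire_variants: Iterable[VariantRecord], cohort_sites
) -> list[VariantRecord]:
    """Remove records whose (chrom, pos, ref, alt) key appears in the cohort.

    Cohort membership is site-level presence/absence; multi-allelic records
    must be pre-split, one alt per record.
    """
    keys = _cohort_keyset(cohort_sites)
    return [v for v in sire_variants if v.site_key not in keys]


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int]]]:
    """Sort and merge possibly-overlapping 1-based closed intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start > end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out = [ivals[0]]
        for s, e in ivals[1:]:
            ls, le = out[-1]
            if s <= le + 1:
                out[-1] = (ls, max(le, e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def restrict_to_intervals(
    variants: Iterable[VariantRecord],
    intervals: Iterable[tuple[str, int, int]],
) -> list[VariantRecord]:
    """Keep records inside any interval (closed boundaries); order preserved."""
    merged = merge_intervals(intervals)
    out = []
    for v in variants:
        for s, e in merged.get(v.chrom, ()):
            if s <= v.pos <= e:
                out.append(v)
                break
    return out
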