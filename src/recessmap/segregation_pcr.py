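"""In-silico PCR genotyping and Mendelian co-segregation testing.

Amplicon prediction is coordinate arithmetic on the reference: a primer
pair yields a product on an allele iff both primer footprints survive the
allele's edits, and the product length is the reference span between the
primers' 5' ends adjusted by each enclosed deletion/insertion.  The printed
5'-start of a reverse primer is taken as its RIGHTMOST reference base — the
unique convention under which the wild-type assay arithmetic closes.

An optional sequence-scan mode matches primer sequences exactly against an
explicit allele sequence instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq
from scipy import stats

from .pedigree import Pedigree

NO_PRODUCT = None

GENOTYPE_WT = "+/+"
GENOTYPE_HET = "+/-"
GENOTYPE_HOM = "-/-"


@dataclass(frozen=True)
class Primer:
    """A PCR primer anchored by its 5' base on the reference.

    For forward primers ``five_prime_pos`` is the leftmost footprint base;
    for reverse primers it is the RIGHTMOST footprint base.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    five_prime_pos: int

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.five_prime_pos < 1:
            raise ValueError("five_prime_pos must be >= 1")
        if not self.sequence:
            raise ValueError("empty primer sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def footprint(self) -> tuple[int, int]:
        if self.orientation == "forward":
            return self.five_prime_pos, self.five_prime_pos + self.length - 1
        return self.five_prime_pos - self.length + 1, self.five_prime_pos


@dataclass(frozen=True)
class Edit:
    """A delins edit: reference bases del_start..del_end replaced by inserted_seq."""

    del_start: int
    del_end: int
    inserted_seq: str = ""

    def __post_init__(self):
        if self.del_start < 1 or self.del_end < self.del_start:
            raise ValueError("invalid edit interval")

    @property
    def deleted_length(self) -> int:
        return self.del_end - self.del_start + 1


@dataclass(frozen=True)
class AlleleModel:
    """An allele as a list of non-overlapping sorted edits; empty = wild type."""

    edits: tuple[Edit, ...] = ()

    def __post_init__(self):
        prev_end = 0
        for e in self.edits:
            if e.del_start <= prev_end:
                raise ValueError("edits must be sorted and non-overlapping")
            prev_end = e.del_end


WILD_TYPE = AlleleModel()


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def amplicon_length(
    forward: Primer,
    reverse: Primer,
    allele: AlleleModel,
    max_product: int = 5000,
) -> Optional[int]:
    """Predicted product length on ``allele``, or ``NO_PRODUCT`` (None).

    No product when either primer footprint overlaps a deleted interval, or
    when the adjusted length exceeds ``max_product`` (practical cycling
    limit).
    """
    if forward.orientation != "forward" or reverse.orientation != "reverse":
        raise ValueError("need one forward and one reverse primer, in that order")
    if forward.five_prime_pos >= reverse.five_prime_pos:
        raise ValueError("forward 5' position must precede reverse 5' position")
    span = (forward.five_prime_pos, reverse.five_prime_pos)
    length = span[1] - span[0] + 1
    for edit in allele.edits:
        edit_iv = (edit.del_start, edit.del_end)
        if not _overlaps(edit_iv, span):
            continue
        if _overlaps(edit_iv, forward.footprint) or _overlaps(edit_iv, reverse.footprint):
            return NO_PRODUCT
        # edit is now fully between the primer footprints
        length += len(edit.inserted_seq) - edit.deleted_length
    if length > max_product:
        return NO_PRODUCT
    return length


def amplicon_length_from_sequence(
    forward: Primer,
    reverse: Primer,
    template: str,
    max_product: int = 5000,
) -> Optional[int]:
    """Sequence-scan mode: exact primer matching against an allele sequence.

    The forward primer must occur verbatim; the reverse primer anneals where
    the template matches its reverse complement.  Ambiguous (multiple-hit)
    primers raise; absent primers give no product.
    """
    template = template.upper()
    fwd = forward.sequence.upper()
    rev_site = str(Seq(reverse.sequence.upper()).reverse_complement())
    f_idx = template.find(fwd)
    if f_idx >= 0 and template.find(fwd, f_idx + 1) >= 0:
        raise ValueError(f"forward primer {forward.name} matches more than once")
    r_idx = template.find(rev_site)
    if r_idx >= 0 and template.find(rev_site, r_idx + 1) >= 0:
        raise ValueError(f"reverse primer {reverse.name} matches more than once")
    if f_idx < 0 or r_idx < 0 or r_idx < f_idx:
        return NO_PRODUCT
    length = r_idx + len(rev_site) - f_idx
    if length > max_product:
        return NO_PRODUCT
    return length


def genotype_from_bands(wt_band: bool, del_band: bool) -> str:
    """Genotype from presence of the wild-type and deletion-specific products."""
    if wt_band and del_band:
        return GENOTYPE_HET
    if wt_band:
        return GENOTYPE_WT
    if del_band:
        return GENOTYPE_HOM
    raise ValueError("assay failure: no product in either assay")


def genotype_by_pcr(
    copies: int,
    forward: Primer,
    wt_reverse: Primer,
    mt_reverse: Primer,
    deletion_allele: AlleleModel,
    max_product: int = 5000,
) -> str:
    """Run both assays in silico on an individual carrying ``copies``
    deletion alleles and read the band pattern."""
    if copies not in (0, 1, 2):
        raise ValueError("copies must be 0, 1 or 2")
    alleles = []
    if copies < 2:
        alleles.append(WILD_TYPE)
    if copies > 0:
        alleles.append(deletion_allele)
    wt_band = any(
        amplicon_length(forward, wt_reverse, a, max_product) is not NO_PRODUCT
        for a in alleles
    )
    del_band = any(
        amplicon_length(forward, mt_reverse, a, max_product) is not NO_PRODUCT
        for a in alleles
    )
    return genotype_from_bands(wt_band, del_band)


@dataclass
class CosegregationReport:
    perfect: bool
    violations: list[tuple[str, str]]  # (individual id, rule broken)

    def to_dict(self) -> dict:
        return {"perfect": self.perfect, "violations": list(self.violations)}


def cosegregation_check(
    genotypes: Mapping[str, str],
    pedigree: Pedigree,
) -> CosegregationReport:
    """Check perfect recessive co-segregation of the deletion.

    Perfect iff every affected individual is -/-, every unaffected one is
    +/+ or +/-, and every genotyped parent of an affected individual carries
    at least one deletion allele.
    """
    violations: list[tuple[str, str]] = []
    for ind_id, g in genotypes.items():
        if ind_id not in pedigree:
            raise ValueError(f"genotyped individual {ind_id!r} missing from pedigree")
        ind = pedigree.get(ind_id)
        if ind.affected and g != GENOTYPE_HOM:
            violations.append((ind_id, "affected not homozygous for deletion"))
        if not ind.affected and g == GENOTYPE_HOM:
            violations.append((ind_id, "unaffected homozygous for deletion"))
    obligate = pedigree.obligate_carrier_dams() | pedigree.obligate_carrier_sires()
    for pid in sorted(obligate):
        g = genotypes.get(pid)
        if g == GENOTYPE_WT:
            violations.append((pid, "obligate carrier lacks deletion allele"))
    return CosegregationReport(perfect=not violations, violations=violations)


@dataclass
class SegregationTestResult:
    n_offspring: int
    n_affected: int
    p0: float
    p_value: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def segregation_ratio_test(
    pedigree: Pedigree,
    dam_carrier: Mapping[str, bool],
    p0: float = 0.25,
) -> SegregationTestResult:
    """Exact two-sided binomial test of the recessive segregation ratio.

    Under carrier x carrier matings each offspring is affected with
    probability ``p0`` (0.25 for an autosomal recessive); offspring of
    non-carrier dams have null probability zero, so any affected among them
    is impossible under the null and raises.  The two-sided p-value sums the
    probabilities of outcomes no more likely than the observed one.
    """
    at_risk = 0
    affected = 0
    for ind in pedigree:
        if ind.dam_id is None or ind.dam_id not in dam_carrier:
            continue
        if dam_carrier[ind.dam_id]:
            at_risk += 1
            if ind.affected:
                affected += 1
        elif ind.affected:
            raise ValueError(
                f"affected offspring {ind.id!r} of non-carrier dam: impossible under null"
            )
    if at_risk == 0:
        raise ValueError("no offspring of carrier dams")
    p = stats.binomtest(affected, at_risk, p0, alternative="two-sided").pvalue
    return SegregationTestResult(
        n_offspring=at_risk, n_affected=affected, p0=p0, p_value=float(p)
    )


def population_screen(genotypes: Iterable[str]) -> int:
    """Count carriers (>= 1 deletion allele) in a population sample."""
    return sum(1 for g in genotypes if g in (GENOTYPE_HET, GENOTYPE_HOM))
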