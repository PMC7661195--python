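"""In-silico PCR arithmetic and Mendelian segregation statistics."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recessmap.pedigree import Individual, Pedigree
from recessmap.segregation_pcr import (
    NO_PRODUCT,
    AlleleModel,
    Edit,
    Primer,
    WILD_TYPE,
    amplicon_length,
    amplicon_length_from_sequence,
    cosegregation_check,
    genotype_by_pcr,
    genotype_from_bands,
    population_screen,
    segregation_ratio_test,
)

# the assay: common forward primer, one reverse inside the deletion (wild-type
# product), one reverse downstream of it (deletion-specific product)
DEL_F = Primer("BTA14_Del_F", "TCCCTGAGCCAGTGAATTCC", "forward", 56_450_454)
DEL_WT_R = Primer("BTA14_DelWt_R", "GTGTCCGACTCTGTGTGACC", "reverse", 56_451_423)
DEL_MT_R = Primer("BTA14_DelMt_R", "GCATCAGCGCTAAGAACTGC", "reverse", 56_501_362)
DELETION_ALLELE = AlleleModel((Edit(56_451_029, 56_501_201, "TGACAA"),))


class TestAmpliconLength:
    def test_wild_type_product_is_970(self):
        assert amplicon_length(DEL_F, DEL_WT_R, WILD_TYPE) == 970

    def test_reverse_footprint_inside_deletion_gives_no_product(self):
        assert amplicon_length(DEL_F, DEL_WT_R, DELETION_ALLELE) is NO_PRODUCT

    def test_wild_type_span_beyond_max_product(self):
        # 56,501,362 - 56,450,454 + 1 = 50,909 bp > 5,000
        assert amplicon_length(DEL_F, DEL_MT_R, WILD_TYPE) is NO_PRODUCT

    def test_deletion_specific_product_from_coordinates(self):
        # 575 bp upstream + 6 inserted + 161 downstream
        assert amplicon_length(DEL_F, DEL_MT_R, DELETION_ALLELE) == 575 + 6 + 161

    def test_primer_orientation_and_order_validated(self):
        with pytest.raises(ValueError):
            amplicon_length(DEL_WT_R, DEL_F, WILD_TYPE)
        with pytest.raises(ValueError):
            amplicon_length(DEL_F, Primer("r", "ACGT", "reverse", 56_450_000), WILD_TYPE)

    @given(offset=st.integers(-56_000_000, 10_000_000))
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, offset):
        f = Primer("f", DEL_F.sequence, "forward", DEL_F.five_prime_pos + offset)
        r = Primer("r", DEL_MT_R.sequence, "reverse", DEL_MT_R.five_prime_pos + offset)
        allele = AlleleModel(
            (Edit(56_451_029 + offset, 56_501_201 + offset, "TGACAA"),)
        )
        assert amplicon_length(f, r, allele) == 575 + 6 + 161

    def test_sequence_scan_mode_agrees_with_coordinates(self):
        from Bio.Seq import Seq

        fwd = "TCCCTGAGCCAGTGAATTCC"
        rev = "GTGTCCGACTCTGTGTGACC"
        spacer = "ACGTAG" * 20
        template = "GGGG" + fwd + spacer + str(Seq(rev).reverse_complement()) + "GGGG"
        f = Primer("f", fwd, "forward", 5)
        r = Primer("r", rev, "reverse", 5 + 20 + len(spacer) + 20 - 1)
        by_seq = amplicon_length_from_sequence(f, r, template)
        by_coord = amplicon_length(f, r, WILD_TYPE)
        assert by_seq == by_coord == 20 + len(spacer) + 20

    def test_sequence_scan_absent_primer_no_product(self):
        f = Primer("f", "AAAAAAAAAA", "forward", 1)
        r = Primer("r", "CCCCCCCCCC", "reverse", 100)
        assert amplicon_length_from_sequence(f, r, "ACGT" * 100) is NO_PRODUCT


class TestGenotypeFromBands:
    @pytest.mark.parametrize(
        "wt,dl,expected", [(True, False, "+/+"), (True, True, "+/-"), (False, True, "-/-")]
    )
    def test_band_patterns(self, wt, dl, expected):
        assert genotype_from_bands(wt, dl) == expected

    def test_no_bands_is_assay_failure(self):
        with pytest.raises(ValueError, match="assay failure"):
            genotype_from_bands(False, False)

    @pytest.mark.parametrize("copies,expected", [(0, "+/+"), (1, "+/-"), (2, "-/-")])
    def test_in_silico_assay_recovers_copy_number(self, copies, expected):
        got = genotype_by_pcr(copies, DEL_F, DEL_WT_R, DEL_MT_R, DELETION_ALLELE)
        assert got == expected


def paper_structured_family():
    """Sire +/- mated to five daughters (three carriers); 24 offspring with
    six affected, all from carrier dams."""
    inds = [Individual("sire", None, None, "M")]
    inds += [Individual(f"fdam{i}", None, None, "F") for i in range(1, 6)]
    carriers = {"dam1", "dam2", "dam3"}
    genotypes = {"sire": "+/-"}
    for i in range(1, 6):
        inds.append(Individual(f"dam{i}", "sire", f"fdam{i}", "F"))
        genotypes[f"dam{i}"] = "+/-" if f"dam{i}" in carriers else "+/+"
    k = 0
    # carrier dams: 5 offspring each (2 affected each for dam1/dam2, 2 for dam3)
    layout = {"dam1": (5, 2), "dam2": (5, 2), "dam3": (5, 2), "dam4": (5, 0), "dam5": (4, 0)}
    for dam, (n, n_aff) in layout.items():
        for j in range(n):
            k += 1
            affected = j < n_aff
            inds.append(Individual(f"calf{k}", "sire", dam, "U", affected=affected))
            if affected:
                genotypes[f"calf{k}"] = "-/-"
            elif dam in carriers and j < n_aff + 2:
                genotypes[f"calf{k}"] = "+/-"
            else:
                genotypes[f"calf{k}"] = "+/+"
    return Pedigree(inds), genotypes, {d: d in carriers for d in layout}


class TestCosegregation:
    def test_paper_structured_family_is_perfect(self):
        pedigree, genotypes, _ = paper_structured_family()
        assert sum(g == "-/-" for g in genotypes.values()) == 6
        assert sum(g == "+/-" for g in genotypes.values()) == 1 + 3 + 6
        report = cosegregation_check(genotypes, pedigree)
        assert report.perfect
        assert report.violations == []

    def test_unaffected_homozygote_breaks_perfection(self):
        pedigree, genotypes, _ = paper_structured_family()
        victim = next(k for k, g in genotypes.items() if g == "+/+" and k.startswith("calf"))
        genotypes[victim] = "-/-"
        report = cosegregation_check(genotypes, pedigree)
        assert not report.perfect
        assert (victim, "unaffected homozygous for deletion") in report.violations

    def test_affected_heterozygote_flagged(self):
        pedigree, genotypes, _ = paper_structured_family()
        case = next(k for k, g in genotypes.items() if g == "-/-")
        genotypes[case] = "+/-"
        report = cosegregation_check(genotypes, pedigree)
        assert (case, "affected not homozygous for deletion") in report.violations


def exact_binomial_two_sided(k, n, p0):
    """Independent enumeration: sum of outcome probabilities <= P(observed)."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return sum(p for p in pmf if p <= obs * (1 + 1e-12))


class TestSegregationRatioTest:
    def test_six_of_twentyfour_consistent_with_recessive_ratio(self):
        pedigree, _, dam_carrier = paper_structured_family()
        result = segregation_ratio_test(pedigree, dam_carrier)
        # only carrier-dam offspring are at risk: 15 calves, 6 affected
        assert (result.n_offspring, result.n_affected) == (15, 6)
        assert result.p_value > 0.05
        assert result.p_value == pytest.approx(exact_binomial_two_sided(6, 15, 0.25), rel=1e-9)

    def test_zero_affected_matches_enumeration(self):
        inds = [
            Individual("sire", None, None, "M"),
            Individual("fdam", None, None, "F"),
            Individual("dam", "sire", "fdam", "F"),
        ]
        inds += [Individual(f"c{i}", "sire", "dam", "U") for i in range(24)]
        pedigree = Pedigree(inds)
        result = segregation_ratio_test(pedigree, {"dam": True})
        assert result.p_value == pytest.approx(exact_binomial_two_sided(0, 24, 0.25), rel=1e-9)

    def test_affected_from_noncarrier_dam_impossible_under_null(self):
        inds = [
            Individual("sire", None, None, "M"),
            Individual("fdam", None, None, "F"),
            Individual("dam", "sire", "fdam", "F"),
            Individual("c1", "sire", "dam", "U", affected=True),
        ]
        with pytest.raises(ValueError, match="impossible under null"):
            segregation_ratio_test(Pedigree(inds), {"dam": False})

    def test_no_carrier_dam_offspring_is_an_error(self):
        pedigree = Pedigree([Individual("sire", None, None, "M")])
        with pytest.raises(ValueError, match="no offspring"):
            segregation_ratio_test(pedigree, {})


class TestPopulationScreen:
    def test_absent_from_unrelated_controls(self):
        assert population_screen(["+/+"] * 182) == 0

    def test_counts_carriers(self):
        assert population_screen(["+/+", "+/-", "+/+", "-/-"]) == 2

    def test_empty(self):
        assert population_screen([]) == 0
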