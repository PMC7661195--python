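"""ROH detection against a quadratic brute-force oracle, shared-region
trimming, and pedigree-consistency filtering."""
import numpy as np
import pytest

from conftest import make_matrix
from recessmap.homozygosity_mapping import (
    CandidateRegion,
    RohParams,
    detect_roh,
    filter_regions_by_support,
    merge_candidate_regions,
    pedigree_filter,
    shared_case_regions,
)
from recessmap.pedigree import Individual, Pedigree


def roh_oracle(positions, calls, params):
    """Quadratic enumeration of all valid runs, greedy left-to-right pick.

    A run [i, j] is valid when both ends are homozygous and the interior
    heterozygous/missing counts stay within budget; for each start the
    maximal end is found by exhaustive scan.
    """
    positions = list(positions)
    calls = list(calls)
    n = len(calls)
    hom = [c in (0, 2) for c in calls]
    out = []
    last_end = -1
    for i in range(n):
        if not hom[i] or i <= last_end:
            continue
        j_max = -1
        for j in range(i, n):
            if not hom[j]:
                continue
            inner = calls[i + 1 : j]
            if (
                sum(c == 1 for c in inner) <= params.max_het_per_run
                and sum(c == -1 for c in inner) <= params.max_missing_per_run
            ):
                j_max = j
        n_snps = j_max - i + 1
        length = positions[j_max] - positions[i] + 1
        if n_snps >= params.min_snps or length > params.min_length_bp:
            out.append((positions[i], positions[j_max], n_snps))
            last_end = j_max
    return out


class TestDetectRoh:
    def test_all_heterozygous_yields_nothing(self):
        pos = np.arange(1, 41) * 1000
        assert detect_roh(pos, np.ones(40, dtype=np.int8)) == []

    def test_snp_count_criterion(self):
        # 30 consecutive homozygous SNPs over 80 kb: SNP rule fires, length not
        pos = np.linspace(1, 80_000, 30).astype(int)
        runs = detect_roh(pos, np.zeros(30, dtype=np.int8))
        assert len(runs) == 1
        assert runs[0].n_snps == 30
        assert runs[0].length_bp <= 100_000

    def test_length_criterion(self):
        # 20 homozygous SNPs over 150 kb qualify by length alone
        pos = np.linspace(1, 150_000, 20).astype(int)
        runs = detect_roh(pos, np.full(20, 2, dtype=np.int8))
        assert len(runs) == 1
        assert runs[0].length_bp > 100_000

    def test_tolerated_calls_never_at_run_ends(self):
        params = RohParams(min_snps=3, min_length_bp=10**9)
        pos = np.arange(1, 8) * 100
        calls = np.array([-1, 0, 0, -1, 0, -1, -1], dtype=np.int8)
        runs = detect_roh(pos, calls, params)
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end) == (200, 500)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            detect_roh(np.array([5, 3, 10]), np.zeros(3, dtype=np.int8))

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=n, replace=False))
        calls = rng.choice(
            np.array([-1, 0, 1, 2], dtype=np.int8), size=n, p=[0.05, 0.42, 0.11, 0.42]
        )
        params = RohParams(
            min_snps=int(rng.integers(3, 31)),
            min_length_bp=int(rng.choice([50_000, 100_000])),
            max_missing_per_run=int(rng.integers(0, 3)),
            max_het_per_run=int(rng.integers(0, 2)),
        )
        got = [(r.start, r.end, r.n_snps) for r in detect_roh(pos, calls, params)]
        assert got == roh_oracle(pos, calls, params)


SMALL = RohParams(min_snps=3, min_length_bp=10**9, max_missing_per_run=1)


class TestSharedCaseRegions:
    def test_single_case_regions_are_its_roh(self):
        m = make_matrix([[0, 0, 0, 0, 1, 2, 2, 2]])
        regions = shared_case_regions(m, ["s0"], SMALL)
        assert [(r.start, r.end) for r in regions] == [(1000, 4000), (6000, 8000)]
        assert np.array_equal(regions[0].case_haplotype, [0, 0, 0, 0])
        assert np.array_equal(regions[1].case_haplotype, [2, 2, 2])

    def test_split_at_homozygous_mismatch(self):
        # both cases homozygous throughout, but discordant at SNP 4
        calls = [
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 2, 0, 0, 0],
        ]
        m = make_matrix(calls)
        regions = shared_case_regions(m, ["s0", "s1"], SMALL)
        assert [(r.start, r.end) for r in regions] == [(1000, 3000), (5000, 7000)]

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            shared_case_regions(make_matrix([[0]]), [], SMALL)

    def test_adding_a_case_never_grows_regions(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            calls = rng.choice(
                np.array([-1, 0, 1, 2], dtype=np.int8),
                size=(3, 60),
                p=[0.03, 0.45, 0.07, 0.45],
            )
            m = make_matrix(calls)
            two = shared_case_regions(m, ["s0", "s1"], SMALL)
            three = shared_case_regions(m, ["s0", "s1", "s2"], SMALL)
            for r3 in three:
                assert any(
                    r2.start <= r3.start and r3.end <= r2.end for r2 in two
                ), "a region grew when a case was added"

    def test_default_family_shared_block_contains_deletion(self, family42):
        _, pedigree, matrix, truth = family42
        cases = [i for i in pedigree.affected_ids() if i in matrix.sample_ids]
        regions = shared_case_regions(matrix, cases)
        assert any(
            r.chrom == truth.deletion[0]
            and r.start <= truth.deletion[1]
            and truth.deletion[2] <= r.end
            for r in regions
        )


def _region(matrix, snp_lo, snp_hi, haplotype):
    idx = np.arange(snp_lo, snp_hi + 1)
    return CandidateRegion(
        chrom="1",
        start=int(matrix.pos[snp_lo]),
        end=int(matrix.pos[snp_hi]),
        snp_indices=idx,
        snp_ids=matrix.snp_ids[idx],
        case_haplotype=np.asarray(haplotype, dtype=np.int8),
        n_snps=len(idx),
    )


def _trio_pedigree():
    return Pedigree(
        [
            Individual("sire", None, None, "M"),
            Individual("dam", None, None, "F"),
            Individual("case", "sire", "dam", "F", affected=True),
            Individual("sib", "sire", "dam", "M"),
        ]
    )


class TestPedigreeFilter:
    def test_sib_matching_case_haplotype_excludes_region(self):
        calls = [
            [0, 0, 0],  # case
            [0, 0, 0],  # sib: identical homozygous -> exclusion
            [1, 0, 0],  # dam: heterozygous at SNP 0 -> no exclusion from dam
        ]
        m = make_matrix(calls, sample_ids=["case", "sib", "dam"])
        reg = _region(m, 0, 2, [0, 0, 0])
        surviving = pedigree_filter([reg], m, _trio_pedigree())
        assert surviving == []
        assert reg.support["excluded_by"] == ["sib"]

    def test_discordant_call_rescues_exclusion(self):
        calls = [
            [0, 0, 0],
            [0, 2, 0],  # sib discordant at SNP 1
            [1, 0, 0],
        ]
        m = make_matrix(calls, sample_ids=["case", "sib", "dam"])
        reg = _region(m, 0, 2, [0, 0, 0])
        surviving = pedigree_filter([reg], m, _trio_pedigree())
        assert len(surviving) == 1
        assert reg.support["n_dams_checked"] == 1
        assert reg.support["n_sibs_checked"] == 1

    def test_missing_call_does_not_rescue(self):
        # a no-call carries no evidence of difference: sib still excludes
        calls = [
            [0, 0, 0],
            [0, -1, 0],
            [1, 0, 0],
        ]
        m = make_matrix(calls, sample_ids=["case", "sib", "dam"])
        reg = _region(m, 0, 2, [0, 0, 0])
        assert pedigree_filter([reg], m, _trio_pedigree()) == []


class TestRegionPostprocessing:
    def test_merge_heals_small_gaps_only(self):
        m = make_matrix([[0] * 10], positions=np.arange(1, 11) * 100_000)
        a = _region(m, 0, 2, [0, 0, 0])
        b = _region(m, 4, 6, [0, 0, 0])  # 199,999-bp gap: merged
        c = _region(m, 9, 9, [0])  # 299,999-bp gap: kept apart
        merged = merge_candidate_regions([a, b, c], max_gap_bp=250_000)
        assert [(r.start, r.end) for r in merged] == [(100_000, 700_000), (1_000_000, 1_000_000)]
        assert merged[0].n_snps == 6

    def test_support_floor(self):
        m = make_matrix([[0] * 10])
        a = _region(m, 0, 5, [0] * 6)
        b = _region(m, 8, 9, [0, 0])
        kept = filter_regions_by_support([a, b], min_region_snps=5)
        assert kept == [a]

    def test_end_to_end_candidate_recovery(self, family42):
        from recessmap.genotype_qc import qc_filter

        _, pedigree, matrix, truth = family42
        filtered, _ = qc_filter(matrix)
        cases = [i for i in pedigree.affected_ids() if i in filtered.sample_ids]
        shared = shared_case_regions(filtered, cases)
        surviving = pedigree_filter(shared, filtered, pedigree)
        final = filter_regions_by_support(merge_candidate_regions(surviving))
        assert len(final) == 1
        assert final[0].contains_interval(*truth.deletion)
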