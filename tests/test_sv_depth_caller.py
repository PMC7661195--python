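"""Depth-based deletion caller: segment scan, Welch flank tests, per-base
breakpoint refinement, depth genotyping and discordant-pair clustering."""
import numpy as np
import pytest
from scipy import special, stats

from recessmap.sv_depth_caller import (
    call_deletion,
    cluster_discordant_pairs,
    flank_tests,
    genotype_from_depth,
    refine_breakpoints,
    segment_scan,
)
from recessmap.synthetic_family import (
    DepthProfile,
    FamilyTruth,
    ReadPair,
    simulate_depth,
    simulate_discordant_pairs,
)


def profile_from_counts(counts, window=1000, start=1, chrom="14"):
    counts = np.asarray(counts, dtype=float)
    starts = start + np.arange(len(counts)) * window
    return DepthProfile(chrom, window, starts, counts)


def het_truth():
    return FamilyTruth(
        deletion=("14", 56_451_029, 56_501_201),
        inserted_seq="",
        carrier_status={"sire": 1, "wt": 0},
    )


def welch_reference(a, b):
    """Hand-rolled Welch statistic with Satterthwaite df and p via stdtr."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * special.stdtr(df, -abs(t))
    return t, p


class TestSegmentScan:
    def test_flat_profile_yields_nothing(self):
        rng = np.random.default_rng(0)
        prof = profile_from_counts(rng.poisson(30, size=100))
        assert segment_scan(prof) == []

    def test_single_implanted_dip_recovered(self):
        # 50 windows near 15 in a ~30 background, default noise model
        truth = het_truth()
        prof = simulate_depth(truth, "sire", ("14", 56_350_000, 56_550_000), 30, 1000, seed=3)
        segs = segment_scan(prof)
        assert len(segs) == 1
        assert abs(segs[0].start - 56_451_029) <= 2 * prof.window_size
        assert abs(segs[0].end - 56_501_201) <= 2 * prof.window_size

    def test_two_separated_dips_found_separately(self):
        counts = np.full(120, 30.0)
        counts[20:35] = 14.0
        counts[80:95] = 14.0
        segs = segment_scan(profile_from_counts(counts))
        assert [(s.first_window, s.last_window) for s in segs] == [(20, 34), (80, 94)]

    def test_all_zero_profile_is_an_error(self):
        with pytest.raises(ValueError, match="no baseline coverage"):
            segment_scan(profile_from_counts(np.zeros(100)))

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            segment_scan(profile_from_counts(np.full(20, 30.0)), min_len_windows=10)


class TestFlankTests:
    def test_matches_reference_welch_computation(self):
        counts = np.array([30, 31, 29, 30, 15, 16, 14, 15, 29, 30, 31, 30], float)
        prof = profile_from_counts(counts, window=1000, start=1)
        seg = segment_scan(prof, min_len_windows=4, smooth_windows=1)[0]
        rep = flank_tests(prof, seg, (1, 4000), (8001, 12000))
        assert rep.mean_upstream == 30.0
        assert rep.mean_inside == 15.0
        assert rep.p_up_vs_in < 0.001
        t_ref, p_ref = welch_reference(counts[:4], counts[4:8])
        assert rep.t_up_vs_in == pytest.approx(t_ref, abs=1e-10)
        assert rep.p_up_vs_in == pytest.approx(p_ref, abs=1e-10)

    def test_null_calibration_flanks_from_same_distribution(self):
        # empirical type-I rate at alpha=0.05 stays near nominal (<=10%)
        rejections = 0
        counts = np.zeros(120)
        counts[40:80] = 0  # placeholder; filled per seed below
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = rng.poisson(30, size=120).astype(float)
            c[40:80] = rng.poisson(15, size=40)
            prof = profile_from_counts(c)
            seg = segment_scan(prof, min_len_windows=10)[0]
            rep = flank_tests(prof, seg, (1, 40_000), (81_000, 120_000))
            if rep.p_up_vs_down < 0.05:
                rejections += 1
        assert rejections <= 10

    def test_degenerate_strata_rejected(self):
        counts = np.concatenate(
            [np.full(10, 30.0), np.full(6, 15.0), [30, 31, 29, 30, 31, 30, 29, 31, 30, 29]]
        )
        prof = profile_from_counts(counts)
        seg = segment_scan(prof, min_len_windows=3, smooth_windows=1)[0]
        with pytest.raises(ValueError, match="fewer than 2 windows"):
            flank_tests(prof, seg, (9001, 10_000), (16_001, 26_000))
        with pytest.raises(ValueError, match="zero variance"):
            # the first ten windows are exactly constant
            flank_tests(prof, seg, (1, 10_000), (16_001, 26_000))


class TestWelchAgainstScipy:
    def test_reference_formula_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), rng.integers(3, 40))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), rng.integers(3, 40))
            t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
            t_ref, p_ref = welch_reference(a, b)
            assert abs(t_sp - t_ref) < 1e-10
            assert abs(p_sp - p_ref) < 1e-10


class TestRefineBreakpoints:
    def test_noiseless_step_recovered_exactly(self):
        left_truth, right_truth = 5_000, 12_000
        lo = left_truth - 2000
        hi = right_truth + 2000
        pos = np.arange(lo, hi + 1)
        counts = np.where((pos >= left_truth) & (pos <= right_truth), 15.0, 30.0)
        tracks = [(lo, counts)]
        left, right = refine_breakpoints(tracks, left_truth, right_truth, 1500)
        assert (left, right) == (left_truth, right_truth)

    def test_poisson_noise_high_accuracy(self):
        hits = 0
        for seed in range(20):
            truth = het_truth()
            prof = simulate_depth(
                truth, "sire", ("14", 56_350_000, 56_550_000), 30, 1000, seed=seed
            )
            left, right = refine_breakpoints(prof.per_base, 56_451_029, 56_501_201, 2000)
            if abs(left - 56_451_029) <= 100 and abs(right - 56_501_201) <= 100:
                hits += 1
        assert hits >= 19

    def test_flat_noise_not_resolvable(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(30, size=4001).astype(float)
        with pytest.raises(ValueError, match="not resolvable"):
            refine_breakpoints([(1, counts)], 2000, 2000, 1500)

    def test_missing_track_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="covers"):
            refine_breakpoints([(1, np.ones(100))], 5000, 6000, 500)


class TestGenotypeFromDepth:
    @pytest.mark.parametrize(
        "inside,flank,expected",
        [
            (17.79, 32.98, "+/-"),  # the carrier sire's observed step
            (0.3, 30.0, "-/-"),
            (30.0, 30.0, "+/+"),
            (7.4, 30.0, "-/-"),
            (7.6, 30.0, "+/-"),
            (22.6, 30.0, "+/+"),
        ],
    )
    def test_threshold_classification(self, inside, flank, expected):
        assert genotype_from_depth(inside, flank) == expected

    def test_zero_flank_rejected(self):
        with pytest.raises(ValueError):
            genotype_from_depth(10.0, 0.0)


class TestClusterDiscordantPairs:
    def test_simulated_pairs_recover_deletion_span(self):
        truth = het_truth()  # 50,173 bp deleted
        pairs = simulate_discordant_pairs(truth, 1, 20, 400, 30, seed=5)
        support, span = cluster_discordant_pairs(pairs, 400)
        assert support == 20
        assert abs(span - 50_173) <= 100

    def test_concordant_pairs_give_no_support(self):
        pairs = [ReadPair(1000 + i, 1200 + i, 400) for i in range(10)]
        assert cluster_discordant_pairs(pairs, 400) == (0, None)

    def test_two_deletions_largest_cluster_reported(self):
        truth_a = het_truth()
        truth_b = FamilyTruth(("14", 10_000_000, 10_020_000), "", {"s": 1})
        pairs = simulate_discordant_pairs(truth_a, 1, 12, 400, 30, seed=1)
        pairs += simulate_discordant_pairs(truth_b, 1, 5, 400, 30, seed=2)
        support, span = cluster_discordant_pairs(pairs, 400)
        assert support == 12
        assert abs(span - 50_173) <= 150
        clusters = cluster_discordant_pairs(pairs, 400, return_all=True)
        assert sorted(c.support for c in clusters) == [5, 12]

    def test_empty_input(self):
        assert cluster_discordant_pairs([], 400) == (0, None)


class TestCallDeletion:
    def test_heterozygous_sire_call(self):
        truth = het_truth()
        prof = simulate_depth(
            truth, "sire", ("14", 56_350_000, 56_550_000), 30, 1000, seed=42,
            focal_radius=4000,
        )
        pairs = simulate_discordant_pairs(truth, 1, 20, 400, 30, seed=42)
        call = call_deletion(prof, pairs)
        assert call.genotype == "+/-"
        assert call.pair_support == 20
        assert abs(call.start - 56_451_029) <= 100
        assert abs(call.end - 56_501_201) <= 100
        assert call.report.p_up_vs_in < 0.001
        assert call.report.p_in_vs_down < 0.001
        assert call.report.p_up_vs_down > 0.05
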