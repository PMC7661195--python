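"""Deletion detection from read depth, with discordant-pair corroboration.

The caller works on windowed depth: a deletion shows up as a contiguous run
of windows well below the chromosome-wide median.  The called segment is
tested against its flanks with Welch two-sample t-tests (the deletion should
differ from both flanks, the flanks should not differ from each other),
breakpoints are refined per-base with a two-segment least-squares step fit,
the sample is genotyped from the depth ratio, and read pairs with oversized
apparent inserts corroborate the call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .synthetic_family import DepthProfile, ReadPair


@dataclass
class Segment:
    """A candidate low-depth segment in window coordinates."""

    chrom: str
    start: int  # 1-based, first base of first window
    end: int  # last base of last window
    first_window: int
    last_window: int
    mean_count: float


@dataclass
class CoverageTestReport:
    mean_upstream: float
    mean_inside: float
    mean_downstream: float
    n_upstream: int
    n_inside: int
    n_downstream: int
    t_up_vs_in: float
    p_up_vs_in: float
    t_in_vs_down: float
    p_in_vs_down: float
    t_up_vs_down: float
    p_up_vs_down: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class DeletionCall:
    chrom: str
    start: int  # first deleted base, 1-based
    end: int  # last deleted base, 1-based
    inserted_seq: str = ""
    genotype: str = "+/-"  # +/+ , +/- or -/-
    depth_ratio: float = float("nan")
    report: Optional[CoverageTestReport] = None
    pair_support: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must not exceed end")
        if not np.isnan(self.depth_ratio) and self.depth_ratio < 0:
            raise ValueError("depth_ratio must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def segment_scan(
    profile: DepthProfile,
    min_len_windows: int = 10,
    max_ratio: float = 0.75,
    smooth_windows: int = 15,
) -> list[Segment]:
    """Contiguous runs of >= ``min_len_windows`` windows below
    ``max_ratio`` x the global median window count.

    Two numerical safeguards keep the scan stable under overdispersed
    sequencing noise: the threshold is applied to a running-median of the
    counts (``smooth_windows`` wide, edge-preserving, disabled with 1), and
    the baseline median is re-estimated once after provisionally masking
    low windows, so that a deletion occupying a sizeable share of the
    profile cannot drag its own detection threshold down.
    """
    counts = profile.counts
    if len(counts) < 3 * min_len_windows:
        raise ValueError("profile too short for the requested segment length")
    if smooth_windows > 1:
        from scipy.ndimage import median_filter

        smoothed = median_filter(counts, size=smooth_windows, mode="nearest")
    else:
        smoothed = counts
    baseline = float(np.median(counts))
    if baseline <= 0:
        raise ValueError("no baseline coverage")
    provisional_low = smoothed < max_ratio * baseline
    if provisional_low.any() and not provisional_low.all():
        baseline = float(np.median(counts[~provisional_low]))
    threshold = max_ratio * baseline
    low = smoothed < threshold
    n = len(counts)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1

    half = max(smooth_windows, 2)

    def _polish_edge(center: int, other: int, low_on_right: bool) -> int:
        # re-localize the copy-number step at raw window resolution with a
        # two-segment least-squares fit around the smoothed boundary; the
        # running median blurs the step by up to half the smoothing width
        lo = max(0, center - half)
        hi = min(n - 1, center + half)
        if low_on_right:
            hi = min(hi, other)
        else:
            lo = max(lo, other)
        window = counts[lo : hi + 1]
        if len(window) < 4:
            return center
        try:
            k, improvement, mean_diff = _step_fit(window)
        except ValueError:
            return center
        ok_sign = mean_diff > 0 if low_on_right else mean_diff < 0
        if improvement < 0.1 or not ok_sign:
            return center
        return lo + k if low_on_right else lo + k - 1

    segments: list[Segment] = []
    for i, j in runs:
        i = _polish_edge(i, j, low_on_right=True)
        j = _polish_edge(j, i, low_on_right=False)
        if j - i + 1 < min_len_windows:
            continue
        if segments and i <= segments[-1].last_window:
            continue  # polish collided with the previous segment
        if counts[i : j + 1].mean() >= threshold:
            continue  # the segment as a whole must satisfy the depth criterion
        start, _ = profile.window_interval(i)
        _, end = profile.window_interval(j)
        segments.append(
            Segment(
                chrom=profile.chrom,
                start=start,
                end=end,
                first_window=i,
                last_window=j,
                mean_count=float(counts[i : j + 1].mean()),
            )
        )
    return segments


def _stratum(profile: DepthProfile, interval: tuple[int, int]) -> np.ndarray:
    lo, hi = interval
    w_start = profile.window_starts
    w_end = w_start + profile.window_size - 1
    mask = (w_start >= lo) & (w_end <= hi)
    return profile.counts[mask]


def flank_tests(
    profile: DepthProfile,
    segment: Segment,
    flank_up_interval: Optional[tuple[int, int]] = None,
    flank_down_interval: Optional[tuple[int, int]] = None,
) -> CoverageTestReport:
    """Welch two-sided t-tests of window counts: up vs inside, inside vs
    down, up vs down.

    Default flanks extend ~100 kb upstream and ~50 kb downstream of the
    segment.  Each stratum must contain at least two windows with nonzero
    variance; degenerate strata raise rather than being fudged.
    """
    if flank_up_interval is None:
        flank_up_interval = (segment.start - 100_000, segment.start - 1)
    if flank_down_interval is None:
        flank_down_interval = (segment.end + 1, segment.end + 50_000)
    up = _stratum(profile, flank_up_interval)
    inside = _stratum(profile, (segment.start, segment.end))
    down = _stratum(profile, flank_down_interval)
    for name, arr in (("upstream", up), ("inside", inside), ("downstream", down)):
        if len(arr) < 2:
            raise ValueError(f"{name} stratum has fewer than 2 windows")
        if np.var(arr, ddof=1) == 0:
            raise ValueError(f"{name} stratum has zero variance")
    t_ui, p_ui = stats.ttest_ind(up, inside, equal_var=False)
    t_id, p_id = stats.ttest_ind(inside, down, equal_var=False)
    t_ud, p_ud = stats.ttest_ind(up, down, equal_var=False)
    return CoverageTestReport(
        mean_upstream=float(up.mean()),
        mean_inside=float(inside.mean()),
        mean_downstream=float(down.mean()),
        n_upstream=len(up),
        n_inside=len(inside),
        n_downstream=len(down),
        t_up_vs_in=float(t_ui),
        p_up_vs_in=float(p_ui),
        t_in_vs_down=float(t_id),
        p_in_vs_down=float(p_id),
        t_up_vs_down=float(t_ud),
        p_up_vs_down=float(p_ud),
    )


def _step_fit(counts: np.ndarray) -> tuple[int, float, float]:
    """Best two-segment split of ``counts``.

    Returns (k, improvement, mean_diff) where k is the first index of the
    right segment minimising the total within-segment sum of squares, with
    ties broken to the smallest k; improvement is the relative SSE reduction
    over the no-split fit and mean_diff = mean(left) - mean(right).
    """
    x = np.asarray(counts, dtype=np.float64)
    m = len(x)
    if m < 2:
        raise ValueError("need at least two values for a step fit")
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total1, total2 = c1[-1], c2[-1]
    k = np.arange(1, m)  # split index: left = x[:k], right = x[k:]
    left1 = c1[k - 1]
    left2 = c2[k - 1]
    right1 = total1 - left1
    right2 = total2 - left2
    sse = (left2 - left1**2 / k) + (right2 - right1**2 / (m - k))
    sse_flat = total2 - total1**2 / m
    if sse_flat <= 0:
        raise ValueError("breakpoint not resolvable")  # constant signal
    best = int(np.argmin(sse))  # first minimum -> leftmost split
    k_best = best + 1
    improvement = 1.0 - sse[best] / sse_flat
    mean_diff = float(left1[best] / k_best - right1[best] / (m - k_best))
    return k_best, float(improvement), mean_diff


def _edge_track(
    per_base: Sequence[tuple[int, np.ndarray]], lo: int, hi: int
) -> tuple[int, np.ndarray]:
    for start, counts in per_base:
        end = start + len(counts) - 1
        if start <= lo and hi <= end:
            return start, counts
    raise ValueError(f"no per-base track covers {lo}-{hi}")


def refine_breakpoints(
    per_base: Sequence[tuple[int, np.ndarray]],
    approx_left: int,
    approx_right: int,
    search_radius: int = 2000,
    min_improvement: float = 0.05,
) -> tuple[int, int]:
    """Per-base change-point refinement of both deletion edges.

    Each edge is fit independently with a two-segment least-squares step;
    ties break to the leftmost position.  ``left`` is the first deleted base
    and ``right`` the last deleted base.  If the step fit improves the flat
    fit by less than ``min_improvement`` (relative SSE), or the step has the
    wrong sign, the breakpoint is declared unresolvable.
    """
    if search_radius < 1:
        raise ValueError("search_radius must be positive")

    def _fit(center: int, low_on_right: bool) -> int:
        lo, hi = center - search_radius, center + search_radius
        t_start, t_counts = _edge_track(per_base, lo, hi)
        window = t_counts[lo - t_start : hi - t_start + 1]
        k, improvement, mean_diff = _step_fit(window)
        # deleted side must be the low side: left edge -> low on the right
        expected_sign = mean_diff > 0 if low_on_right else mean_diff < 0
        if improvement < min_improvement or not expected_sign:
            raise ValueError("breakpoint not resolvable")
        if low_on_right:
            return lo + k  # first base of the low right segment
        return lo + k - 1  # last base of the low left segment

    left = _fit(approx_left, low_on_right=True)
    right = _fit(approx_right, low_on_right=False)
    return left, right


def genotype_from_depth(
    inside_mean: float,
    flank_mean: float,
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> str:
    """Copy-number genotype from the depth ratio inside/flank.

    Thresholds are the midpoints between the copy-number expectations 0, 0.5
    and 1: ratio < 0.25 -> -/-, 0.25..0.75 -> +/-, > 0.75 -> +/+.
    """
    if flank_mean <= 0:
        raise ValueError("flank_mean must be positive")
    lo, hi = thresholds
    r = inside_mean / flank_mean
    if r < lo:
        return "-/-"
    if r <= hi:
        return "+/-"
    return "+/+"


def apparent_insert(pair: ReadPair, read_len: int = 100) -> int:
    """Reference-scale fragment length implied by a mapped pair."""
    return pair.right_start - pair.left_end - 1 + 2 * read_len


@dataclass
class PairCluster:
    support: int
    implied_deletion_length: float
    left_end_max: int
    right_start_min: int
    pairs: list[ReadPair] = field(default_factory=list)


def cluster_discordant_pairs(
    pairs: Sequence[ReadPair],
    nominal_insert_mean: float,
    insert_sd: float = 30.0,
    read_len: int = 100,
    return_all: bool = False,
):
    """Cluster pairs whose apparent insert exceeds nominal by > 4 SD.

    Discordant pairs are grouped by overlap of their spanned interval
    ``[left_end, right_start]``; each cluster's member count and median
    implied deletion length (apparent insert minus nominal) are reported.
    Returns ``(support, implied_length)`` for the largest cluster — ``(0,
    None)`` when nothing is discordant — or all clusters with
    ``return_all=True``.
    """
    cutoff = nominal_insert_mean + 4 * insert_sd
    disc = [p for p in pairs if apparent_insert(p, read_len) > cutoff]
    if not disc:
        return [] if return_all else (0, None)
    disc.sort(key=lambda p: (p.left_end, p.right_start))
    clusters: list[list[ReadPair]] = [[disc[0]]]
    reach = disc[0].right_start
    for p in disc[1:]:
        if p.left_end <= reach:  # overlaps the current cluster's span
            clusters[-1].append(p)
            reach = max(reach, p.right_start)
        else:
            clusters.append([p])
            reach = p.right_start
    out = []
    for members in clusters:
        spans = [apparent_insert(p, read_len) - nominal_insert_mean for p in members]
        out.append(
            PairCluster(
                support=len(members),
                implied_deletion_length=float(np.median(spans)),
                left_end_max=max(p.left_end for p in members),
                right_start_min=min(p.right_start for p in members),
                pairs=members,
            )
        )
    if return_all:
        return out
    best = max(out, key=lambda c: c.support)
    return best.support, best.implied_deletion_length


def call_deletion(
    profile: DepthProfile,
    pairs: Sequence[ReadPair] = (),
    inserted_seq: str = "",
    min_len_windows: int = 10,
    max_ratio: float = 0.75,
    search_radius: int = 2000,
    nominal_insert_mean: float = 400.0,
    insert_sd: float = 30.0,
) -> DeletionCall:
    """Full depth-caller pass: scan, test, refine, genotype, corroborate."""
    segments = segment_scan(profile, min_len_windows, max_ratio)
    if not segments:
        raise ValueError("no low-depth segment detected")
    seg = max(segments, key=lambda s: s.end - s.start)
    report = flank_tests(profile, seg)
    start, end = seg.start, seg.end
    if profile.per_base:
        try:
            start, end = refine_breakpoints(
                profile.per_base, seg.start, seg.end, search_radius
            )
        except ValueError:
            pass  # keep window-resolution breakpoints
    flank_mean = (report.mean_upstream + report.mean_downstream) / 2
    genotype = genotype_from_depth(report.mean_inside, flank_mean)
    support, _ = cluster_discordant_pairs(pairs, nominal_insert_mean, insert_sd)
    return DeletionCall(
        chrom=profile.chrom,
        start=start,
        end=end,
        inserted_seq=inserted_seq,
        genotype=genotype,
        depth_ratio=report.mean_inside / flank_mean,
        report=report,
        pair_support=support,
    )
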