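"""Runs-of-homozygosity detection and shared-haplotype candidate mapping.

In a single-generation backcross, the chromosomal segment carrying a
recessive lesion is identical by descent in every affected individual, so
all cases are homozygous for the same alleles across it.  This module scans
each case for runs of homozygosity (ROH), intersects the runs across cases
requiring identical homozygous genotypes, and removes regions contradicted
by obligate-carrier dams or unaffected siblings.

ROH semantics are an exact maximal-run scan (not a sliding-window
heuristic): a run starts and ends on homozygous calls and tolerates a
bounded number of missing and heterozygous calls in its interior.  A run
qualifies when it contains at least ``min_snps`` SNPs OR spans more than
``min_length_bp``.  Runs are reported greedily left to right, so the output
is sorted and non-overlapping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .synthetic_family import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class RohParams:
    min_snps: int = 30
    min_length_bp: int = 100_000
    max_missing_per_run: int = 2
    max_het_per_run: int = 0

    def __post_init__(self):
        if min(
            self.min_snps,
            self.min_length_bp,
            self.max_missing_per_run,
            self.max_het_per_run,
        ) < 0:
            raise ValueError("ROH parameters must be non-negative")


@dataclass(frozen=True)
class RohInterval:
    """A qualifying run of homozygosity.

    ``start``/``end`` are the positions of the first and last SNP of the run
    (1-based inclusive); ``start_idx``/``end_idx`` index into the per-
    chromosome SNP arrays the run was detected on.
    """

    chrom: str
    start: int
    end: int
    n_snps: int
    start_idx: int
    end_idx: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class CandidateRegion:
    """An interval where all cases share one homozygous haplotype.

    ``case_haplotype`` holds the shared homozygous call per SNP (-1 where the
    consensus is undefined because every case had a tolerated missing call).
    ``snp_indices`` index into the genotype matrix the region was derived
    from.  ``support`` is filled by the pedigree filter.
    """

    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray
    snp_ids: np.ndarray
    case_haplotype: np.ndarray
    n_snps: int
    support: dict = field(default_factory=dict)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= start and end <= self.end


def _is_hom(calls: np.ndarray) -> np.ndarray:
    return (calls == HOM_REF) | (calls == HOM_ALT)


def detect_roh(
    positions: np.ndarray,
    calls: np.ndarray,
    params: RohParams = RohParams(),
    chrom: str = "?",
) -> list[RohInterval]:
    """Scan one chromosome of one sample for qualifying ROH.

    Greedy left-to-right maximal extension: from each homozygous SNP not yet
    covered, the run is extended rightward while the interior missing/het
    budgets hold; the run ends at the last homozygous SNP reached.  Budgets
    are counted over everything scanned, so tolerated calls never sit at run
    ends.
    """
    positions = np.asarray(positions)
    calls = np.asarray(calls)
    if len(positions) != len(calls):
        raise ValueError("positions/calls length mismatch")
    if len(positions) > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted strictly increasing")

    hom = _is_hom(calls)
    het = calls == HET
    miss = calls == MISSING
    n = len(calls)
    runs: list[RohInterval] = []
    last_end = -1
    for i in np.flatnonzero(hom):
        if i <= last_end:
            continue
        het_c = miss_c = 0
        j_best = int(i)
        j = int(i) + 1
        while j < n:
            if het[j]:
                if het_c + 1 > params.max_het_per_run:
                    break
                het_c += 1
            elif miss[j]:
                if miss_c + 1 > params.max_missing_per_run:
                    break
                miss_c += 1
            else:
                j_best = j
            j += 1
        n_snps = j_best - int(i) + 1
        length = int(positions[j_best]) - int(positions[i]) + 1
        if n_snps >= params.min_snps or length > params.min_length_bp:
            runs.append(
                RohInterval(chrom, int(positions[i]), int(positions[j_best]), n_snps, int(i), j_best)
            )
            last_end = j_best
    return runs


def detect_roh_sample(
    matrix: GenotypeMatrix,
    sample_id: str,
    params: RohParams = RohParams(),
) -> list[RohInterval]:
    """ROH for one sample over every chromosome of the matrix."""
    calls = matrix.calls_for(sample_id)
    out: list[RohInterval] = []
    for chrom in matrix.chrom_order():
        mask = matrix.chrom_mask(chrom)
        idx = np.flatnonzero(mask)
        runs = detect_roh(matrix.pos[mask], calls[mask], params, chrom=chrom)
        # re-anchor slice-local indices to matrix-global ones
        out.extend(
            RohInterval(
                r.chrom,
                r.start,
                r.end,
                r.n_snps,
                int(idx[r.start_idx]),
                int(idx[r.end_idx]),
            )
            for r in runs
        )
    return out


def _intersect_two(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_case_regions(
    matrix: GenotypeMatrix,
    case_ids: list[str],
    params: RohParams = RohParams(),
    roh_by_case: Optional[dict[str, list[RohInterval]]] = None,
) -> list[CandidateRegion]:
    """Intersect the cases' ROH and trim to identically-homozygous stretches.

    Within each interval where every case has a qualifying run, SNPs are kept
    while all non-missing case calls are the same homozygous genotype; any
    heterozygous call or homozygous mismatch splits the interval.  Surviving
    sub-intervals are re-checked against ``params`` and trimmed to SNPs with
    a defined consensus.
    """
    if not case_ids:
        raise ValueError("at least one case required")
    if roh_by_case is None:
        roh_by_case = {c: detect_roh_sample(matrix, c, params) for c in case_ids}

    case_calls = np.stack([matrix.calls_for(c) for c in case_ids])
    regions: list[CandidateRegion] = []
    for chrom in matrix.chrom_order():
        per_case = [
            [(r.start, r.end) for r in roh_by_case[c] if r.chrom == chrom]
            for c in case_ids
        ]
        inter = per_case[0]
        for other in per_case[1:]:
            inter = _intersect_two(inter, other)
        if not inter:
            continue
        mask = matrix.chrom_mask(chrom)
        idx = np.flatnonzero(mask)
        pos = matrix.pos[mask]
        for lo, hi in inter:
            a = int(np.searchsorted(pos, lo, side="left"))
            b = int(np.searchsorted(pos, hi, side="right")) - 1
            if b < a:
                continue
            sub = case_calls[:, idx[a : b + 1]]
            # per-SNP status: bad splits; consensus is the shared hom call
            any_het = (sub == HET).any(axis=0)
            non_missing = sub >= 0
            # max/min over non-missing; equal iff all non-missing agree
            filled_max = np.where(non_missing, sub, -2).max(axis=0)
            filled_min = np.where(non_missing, sub, 3).min(axis=0)
            has_call = non_missing.any(axis=0)
            mismatch = has_call & (filled_max != filled_min)
            bad = any_het | mismatch
            consensus = np.where(has_call, filled_max, MISSING).astype(np.int8)
            regions.extend(
                _regions_from_good_runs(
                    chrom, pos[a : b + 1], idx[a : b + 1], consensus, bad, matrix, params
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _regions_from_good_runs(
    chrom: str,
    pos: np.ndarray,
    global_idx: np.ndarray,
    consensus: np.ndarray,
    bad: np.ndarray,
    matrix: GenotypeMatrix,
    params: RohParams,
) -> list[CandidateRegion]:
    out: list[CandidateRegion] = []
    n = len(pos)
    i = 0
    while i < n:
        if bad[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not bad[j + 1]:
            j += 1
        # trim ends to SNPs with a defined consensus call
        a, b = i, j
        while a <= b and consensus[a] == MISSING:
            a += 1
        while b >= a and consensus[b] == MISSING:
            b -= 1
        if a <= b:
            n_snps = b - a + 1
            length = int(pos[b]) - int(pos[a]) + 1
            if n_snps >= params.min_snps or length > params.min_length_bp:
                sel = global_idx[a : b + 1]
                out.append(
                    CandidateRegion(
                        chrom=chrom,
                        start=int(pos[a]),
                        end=int(pos[b]),
                        snp_indices=np.asarray(sel),
                        snp_ids=matrix.snp_ids[sel],
                        case_haplotype=consensus[a : b + 1].copy(),
                        n_snps=n_snps,
                    )
                )
        i = j + 1
    return out


def pedigree_filter(
    regions: list[CandidateRegion],
    matrix: GenotypeMatrix,
    pedigree,
) -> list[CandidateRegion]:
    """Drop regions compatible with an unaffected relative being autozygous.

    A region is excluded when any obligate-carrier dam, or any unaffected
    sibling of a case, matches the case haplotype homozygously at every
    region SNP where that relative has a call.  A single discordant call
    anywhere rescues the region from that individual — full-penetrance
    recessive logic.  Missing calls carry no evidence either way: they
    neither rescue nor establish a match, and relatives with no calls in the
    region (like wholly ungenotyped ones) contribute no exclusion.

    Every input region gets a ``support`` dict recording the relatives
    checked and any excluding individuals; the surviving regions are
    returned.
    """
    sample_set = set(matrix.sample_ids)
    dams = sorted(pedigree.obligate_carrier_dams() & sample_set)
    sibs = sorted(pedigree.unaffected_sibs_of_affected() & sample_set)
    surviving: list[CandidateRegion] = []
    for reg in regions:
        defined = reg.case_haplotype >= 0
        excluded_by: list[str] = []
        if defined.any():
            hap = reg.case_haplotype[defined]
            snps = reg.snp_indices[defined]
            for sid in dams + sibs:
                calls = matrix.calls_for(sid)[snps]
                has_call = calls >= 0
                if has_call.any() and np.all(calls[has_call] == hap[has_call]):
                    excluded_by.append(sid)
        reg.support = {
            "n_dams_checked": len(dams),
            "n_sibs_checked": len(sibs),
            "excluded_by": excluded_by,
        }
        if not excluded_by:
            surviving.append(reg)
    return surviving


def filter_regions_by_support(
    regions: list[CandidateRegion],
    min_region_snps: int = 30,
) -> list[CandidateRegion]:
    """Keep candidate regions supported by at least ``min_region_snps`` SNPs.

    At ~50-kb marker spacing any 2-3 adjacent SNPs identical-homozygous by
    chance span more than 100 kb, so isolated chance-identity islands would
    otherwise flood the candidate list; a credible mapping interval needs
    marker support on the order of the single-run SNP criterion.
    """
    if min_region_snps < 0:
        raise ValueError("min_region_snps must be non-negative")
    return [r for r in regions if r.n_snps >= min_region_snps]


def merge_candidate_regions(
    regions: list[CandidateRegion],
    max_gap_bp: int = 1_000_000,
) -> list[CandidateRegion]:
    """Merge same-chromosome regions separated by at most ``max_gap_bp``.

    Isolated genotyping errors and missing calls fragment one true
    identical-by-descent region into adjacent pieces; merging heals the
    fragmentation while leaving distant (independent) regions apart.  SNPs in
    the merged gaps are not part of the haplotype signature.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be non-negative")
    by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[CandidateRegion] = []
    for chrom in by_chrom:
        group = sorted(by_chrom[chrom], key=lambda r: r.start)
        current = group[0]
        for nxt in group[1:]:
            if nxt.start - current.end - 1 <= max_gap_bp:
                current = CandidateRegion(
                    chrom=chrom,
                    start=current.start,
                    end=max(current.end, nxt.end),
                    snp_indices=np.concatenate([current.snp_indices, nxt.snp_indices]),
                    snp_ids=np.concatenate([current.snp_ids, nxt.snp_ids]),
                    case_haplotype=np.concatenate(
                        [current.case_haplotype, nxt.case_haplotype]
                    ),
                    n_snps=current.n_snps + nxt.n_snps,
                    support={
                        k: current.support.get(k)
                        for k in current.support
                    },
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda r: (r.chrom, r.start))
    return merged
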