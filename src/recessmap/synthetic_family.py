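"""Synthetic backcross-family generator with known ground truth.

Emulates the data situation of a recessive-lesion mapping study in a
livestock family: a founder sire heterozygous for a large deletion is mated
to several of its own daughters, SNP-chip genotypes are collected on a
~50k-density panel, and the sire's genome is sequenced to ~30x.  Every
generator here is seeded and bit-reproducible, and returns the implanted
truth alongside the data so downstream stages (QC, ROH mapping, depth-based
SV calling, PCR segregation) can be tested end to end without external data.

Coordinates are 1-based fully-closed intervals throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree

# genotype call codes: count of B alleles; -1 = no call
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """Marker panel and recombination model for a simulated population.

    ``allele_freqs`` holds the reference (A) allele frequency per SNP;
    ``recomb_rate`` is expected crossovers per bp (1e-8 = 1 cM/Mb).
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_positions: dict[str, np.ndarray]
    allele_freqs: dict[str, np.ndarray]
    recomb_rate: float = 1e-8

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            pos = np.asarray(self.snp_positions[name])
            freq = np.asarray(self.allele_freqs[name])
            if pos.ndim != 1 or len(pos) != len(freq):
                raise ValueError(f"positions/frequencies mismatch on {name}")
            if len(pos) and (pos[0] < 1 or pos[-1] > length):
                raise ValueError(f"positions outside chromosome {name}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {name}")
            if np.any(freq <= 0) or np.any(freq >= 1):
                raise ValueError("allele frequencies must lie in (0, 1)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")

    def chrom_length(self, name: str) -> int:
        for cname, length in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(name)

    @property
    def chrom_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def n_snps(self) -> int:
        return sum(len(self.snp_positions[c]) for c in self.chrom_names)


@dataclass(frozen=True)
class FamilyTruth:
    """Implanted ground truth: the deletion and per-individual allele count."""

    deletion: tuple[str, int, int]  # (chrom, start, end), 1-based inclusive
    inserted_seq: str
    carrier_status: dict[str, int]  # id -> copies of the deletion allele

    def __post_init__(self):
        chrom, start, end = self.deletion
        if start > end or start < 1:
            raise ValueError("invalid deletion interval")
        if any(c not in "ACGT" for c in self.inserted_seq):
            raise ValueError("inserted_seq must be over {A,C,G,T}")
        for ind, copies in self.carrier_status.items():
            if copies not in (0, 1, 2):
                raise ValueError(f"carrier status of {ind!r} must be 0, 1 or 2")

    @property
    def deletion_length(self) -> int:
        return self.deletion[2] - self.deletion[1] + 1


@dataclass(eq=False)
class GenotypeMatrix:
    """Samples x SNPs biallelic calls; calls are B-allele counts, -1 missing."""

    sample_ids: list[str]
    chrom: np.ndarray  # per-SNP chromosome name
    pos: np.ndarray  # per-SNP 1-based position
    snp_ids: np.ndarray
    calls: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("calls shape inconsistent with samples/SNPs")
        if len(self.chrom) != len(self.pos) or len(self.snp_ids) != len(self.pos):
            raise ValueError("SNP index arrays have inconsistent lengths")
        bad = ~np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def calls_for(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def chrom_order(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return seen

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def select_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            snp_ids=self.snp_ids[mask],
            calls=self.calls[:, mask],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class DepthProfile:
    """Windowed (and optionally per-base) read counts over one chromosome.

    ``per_base`` holds focal per-base tracks as ``(start_pos, counts)``
    tuples, one per breakpoint neighbourhood.
    """

    chrom: str
    window_size: int
    window_starts: np.ndarray  # 1-based, tiling without overlap
    counts: np.ndarray
    per_base: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if len(self.window_starts) != len(self.counts):
            raise ValueError("window_starts/counts length mismatch")
        if len(self.window_starts) > 1:
            if np.any(np.diff(self.window_starts) != self.window_size):
                raise ValueError("windows must tile the segment without overlap")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def window_interval(self, i: int) -> tuple[int, int]:
        s = int(self.window_starts[i])
        return s, s + self.window_size - 1


@dataclass(frozen=True)
class ReadPair:
    """A mapped read pair summarised by its inner coordinates.

    ``left_end`` is the rightmost base of the left read, ``right_start`` the
    leftmost base of the right read; ``nominal_insert`` is the fragment
    length the pair was drawn with on its allele of origin.
    """

    left_end: int
    right_start: int
    nominal_insert: int

    def __post_init__(self):
        if self.right_start <= self.left_end:
            raise ValueError("right_start must exceed left_end")


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n > length:
        raise ValueError("more SNPs requested than available positions")
    for _ in range(1000):
        draw = rng.integers(1, length + 1, size=n)
        uniq = np.unique(draw)
        if len(uniq) == n:
            return uniq
    raise RuntimeError("failed to draw unique SNP positions")


def simulate_population(
    n_chroms: int,
    chrom_length: int,
    n_snps_per_chrom: int,
    seed: int,
    *,
    freq_range: tuple[float, float] = (0.05, 0.5),
    recomb_rate: float = 1e-8,
    chrom_names: Optional[Sequence[str]] = None,
) -> PopulationModel:
    """Draw a marker panel: uniform SNP placement, Uniform(0.05, 0.5) MAF."""
    if n_chroms < 1 or chrom_length <= 0:
        raise ValueError("n_chroms and chrom_length must be positive")
    if n_snps_per_chrom < 2:
        raise ValueError("need at least 2 SNPs per chromosome")
    if chrom_names is None:
        chrom_names = [str(i + 1) for i in range(n_chroms)]
    elif len(chrom_names) != n_chroms:
        raise ValueError("chrom_names length must equal n_chroms")

    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    for name in chrom_names:
        positions[name] = _unique_positions(rng, chrom_length, n_snps_per_chrom)
        freqs[name] = rng.uniform(freq_range[0], freq_range[1], size=n_snps_per_chrom)
    return PopulationModel(
        chromosomes=tuple((name, chrom_length) for name in chrom_names),
        snp_positions=positions,
        allele_freqs=freqs,
        recomb_rate=recomb_rate,
    )


# ---------------------------------------------------------------------------
# backcross family
# ---------------------------------------------------------------------------


class _Genome:
    """Two haplotypes (per-chrom 0/1 allele arrays) plus deletion flags."""

    __slots__ = ("haps", "flags")

    def __init__(self, haps, flags):
        self.haps = haps  # [dict chrom -> uint8 array, dict]
        self.flags = flags  # [bool, bool]: haplotype carries the deletion


def _founder(rng: np.random.Generator, model: PopulationModel, carrier_hap: Optional[int] = None) -> _Genome:
    haps = []
    for _ in range(2):
        h = {}
        for name in model.chrom_names:
            f = model.allele_freqs[name]
            # allele 1 = B drawn with probability 1 - f (f is the A frequency)
            h[name] = (rng.random(len(f)) >= f).astype(np.uint8)
        haps.append(h)
    flags = [carrier_hap == 0, carrier_hap == 1]
    return _Genome(haps, flags)


def _gamete(
    rng: np.random.Generator,
    parent: _Genome,
    model: PopulationModel,
    del_chrom: Optional[str],
    del_point: Optional[int],
) -> tuple[dict, bool]:
    """One meiosis: Poisson crossovers, uniform positions, no interference."""
    alleles: dict[str, np.ndarray] = {}
    carries = False
    for name, length in model.chromosomes:
        pos = model.snp_positions[name]
        n_x = rng.poisson(length * model.recomb_rate)
        cross = np.sort(rng.integers(1, length + 1, size=n_x))
        first = int(rng.integers(2))
        phase = (first + np.searchsorted(cross, pos, side="right")) % 2
        alleles[name] = np.where(
            phase == 0, parent.haps[0][name], parent.haps[1][name]
        ).astype(np.uint8)
        if name == del_chrom and del_point is not None:
            ph = (first + int(np.searchsorted(cross, del_point, side="right"))) % 2
            carries = parent.flags[ph]
    return alleles, bool(carries)


def _gamete_genome(alleles: dict, carries: bool) -> tuple[dict, bool]:
    return alleles, carries


def simulate_backcross(
    model: PopulationModel,
    deletion_interval: tuple[str, int, int],
    inserted_seq: str,
    n_dams: int = 5,
    n_offspring_per_dam: int | Sequence[int] = 5,
    seed: int = 0,
    *,
    error_rate: float = 0.002,
    missing_rate: float = 0.01,
    n_carrier_dams: Optional[int] = None,
    min_affected: int = 0,
    n_genotyped_cases: Optional[int] = None,
    n_genotyped_unaffected: Optional[int] = None,
    max_attempts: int = 10_000,
) -> tuple[Pedigree, GenotypeMatrix, FamilyTruth]:
    """Simulate sire x daughters backcross with an implanted heterozygous deletion.

    The sire carries the deletion on one haplotype.  Daughters arise from the
    sire and unrelated founder dams; offspring from daughter x sire matings.
    An offspring is affected iff it inherits two deletion copies.  SNP calls
    get symmetric call-flip errors (``error_rate``) and independent
    missingness (``missing_rate``).

    ``n_carrier_dams`` forces exactly that many daughters to carry the
    deletion (``None`` = unconditioned Mendelian transmission);
    ``min_affected`` rejection-samples the offspring generation until at
    least that many affected calves exist.  ``n_genotyped_cases`` /
    ``n_genotyped_unaffected`` restrict which offspring contribute genotypes
    (``None`` = all offspring genotyped).
    """
    del_chrom, del_start, del_end = deletion_interval
    if del_chrom not in model.chrom_names:
        raise ValueError(f"deletion chromosome {del_chrom!r} not in model")
    if not (1 <= del_start <= del_end <= model.chrom_length(del_chrom)):
        raise ValueError("deletion interval off chromosome")
    if n_dams < 1:
        raise ValueError("need at least one dam")
    if isinstance(n_offspring_per_dam, int):
        counts = [n_offspring_per_dam] * n_dams
    else:
        counts = list(n_offspring_per_dam)
        if len(counts) != n_dams:
            raise ValueError("n_offspring_per_dam length must equal n_dams")
    if any(c < 0 for c in counts):
        raise ValueError("offspring counts must be non-negative")
    if n_carrier_dams is not None and not (0 <= n_carrier_dams <= n_dams):
        raise ValueError("n_carrier_dams out of range")

    rng = np.random.default_rng(seed)
    del_point = (del_start + del_end) // 2

    sire = _founder(rng, model, carrier_hap=0)
    founder_dams = [_founder(rng, model) for _ in range(n_dams)]

    # daughters: sire x founder dam; optionally force carrier count
    want: Optional[np.ndarray] = None
    if n_carrier_dams is not None:
        want = np.zeros(n_dams, dtype=bool)
        want[rng.choice(n_dams, size=n_carrier_dams, replace=False)] = True
    daughters: list[_Genome] = []
    for i in range(n_dams):
        for _ in range(max_attempts):
            g_s, c_s = _gamete(rng, sire, model, del_chrom, del_point)
            if want is None or c_s == want[i]:
                break
        else:  # pragma: no cover - 0.5 acceptance probability
            raise RuntimeError("carrier-status rejection sampling failed")
        g_d, _ = _gamete(rng, founder_dams[i], model, del_chrom, del_point)
        daughters.append(_Genome([g_s, g_d], [c_s, False]))

    # offspring: daughter x sire; rejection-sample the whole generation
    # until the affected count reaches min_affected
    for _ in range(max_attempts):
        offspring: list[tuple[int, _Genome, int]] = []  # (dam index, genome, copies)
        n_affected = 0
        for i, daughter in enumerate(daughters):
            for _ in range(counts[i]):
                g1, c1 = _gamete(rng, sire, model, del_chrom, del_point)
                g2, c2 = _gamete(rng, daughter, model, del_chrom, del_point)
                copies = int(c1) + int(c2)
                if copies == 2:
                    n_affected += 1
                offspring.append((i, _Genome([g1, g2], [c1, c2]), copies))
        if n_affected >= min_affected:
            break
    else:
        raise RuntimeError(
            f"could not reach min_affected={min_affected} in {max_attempts} attempts"
        )

    # --- pedigree assembly -------------------------------------------------
    individuals: list[Individual] = []
    individuals.append(Individual("sire", None, None, "M", False, True))
    for i in range(n_dams):
        individuals.append(Individual(f"fdam{i + 1}", None, None, "F", False, False))
    dam_ids = [f"dam{i + 1}" for i in range(n_dams)]
    for i, did in enumerate(dam_ids):
        individuals.append(Individual(did, "sire", f"fdam{i + 1}", "F", False, True))

    affected_ids: list[str] = []
    unaffected_ids: list[str] = []
    calf_entries: list[tuple[str, int, _Genome, int]] = []
    for k, (i, genome, copies) in enumerate(offspring):
        cid = f"calf{k + 1}"
        calf_entries.append((cid, i, genome, copies))
        (affected_ids if copies == 2 else unaffected_ids).append(cid)

    genotyped_cases = set(affected_ids)
    if n_genotyped_cases is not None:
        if n_genotyped_cases > len(affected_ids):
            raise RuntimeError("fewer affected offspring than requested genotyped cases")
        genotyped_cases = set(
            rng.choice(affected_ids, size=n_genotyped_cases, replace=False)
        )
    genotyped_unaff = set(unaffected_ids)
    if n_genotyped_unaffected is not None:
        if n_genotyped_unaffected > len(unaffected_ids):
            raise RuntimeError("fewer unaffected offspring than requested genotyped sibs")
        genotyped_unaff = set(
            rng.choice(unaffected_ids, size=n_genotyped_unaffected, replace=False)
        )

    sex_draw = rng.choice(["M", "F"], size=len(calf_entries))
    for k, (cid, i, genome, copies) in enumerate(calf_entries):
        avail = cid in genotyped_cases or cid in genotyped_unaff
        individuals.append(
            Individual(cid, "sire", dam_ids[i], str(sex_draw[k]), copies == 2, avail)
        )
    pedigree = Pedigree(individuals)

    # --- truth -------------------------------------------------------------
    carrier_status: dict[str, int] = {"sire": 1}
    for i in range(n_dams):
        carrier_status[f"fdam{i + 1}"] = 0
        carrier_status[dam_ids[i]] = int(daughters[i].flags[0])
    for cid, _, _, copies in calf_entries:
        carrier_status[cid] = copies
    truth = FamilyTruth(deletion_interval, inserted_seq, carrier_status)

    # --- genotype matrix ---------------------------------------------------
    genomes: dict[str, _Genome] = {"sire": sire}
    for i, did in enumerate(dam_ids):
        genomes[did] = daughters[i]
    for cid, _, genome, _ in calf_entries:
        genomes[cid] = genome

    sample_ids = [ind.id for ind in pedigree if ind.available]
    chrom_col: list[str] = []
    pos_col: list[int] = []
    id_col: list[str] = []
    for name in model.chrom_names:
        for p in model.snp_positions[name]:
            chrom_col.append(name)
            pos_col.append(int(p))
            id_col.append(f"SNP_{name}_{p}")
    calls = np.empty((len(sample_ids), len(pos_col)), dtype=np.int8)
    for r, sid in enumerate(sample_ids):
        genome = genomes[sid]
        row = np.concatenate(
            [
                genome.haps[0][name].astype(np.int8) + genome.haps[1][name]
                for name in model.chrom_names
            ]
        )
        calls[r] = row
    # symmetric call-flip errors, then independent missingness
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls[miss] = MISSING

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chrom_col, dtype=object),
        pos=np.array(pos_col, dtype=np.int64),
        snp_ids=np.array(id_col, dtype=object),
        calls=calls,
    )
    return pedigree, matrix, truth


# default study conditions: 2 chromosomes at 50k-chip marker density, a
# ~50-kb deletion implanted on chromosome "14", family of 5 dams / 24 calves
DEFAULT_DELETION = ("14", 56_451_029, 56_501_201)
DEFAULT_INSERTED_SEQ = "TGACAA"
DEFAULT_CHROM_LENGTH = 80_000_000
DEFAULT_SNPS_PER_CHROM = 1500


def default_family(
    seed: int,
) -> tuple[PopulationModel, Pedigree, GenotypeMatrix, FamilyTruth]:
    """The default study family: 5 dams (3 carriers), 24 calves, >=3 affected,
    3 genotyped cases and 9 genotyped unaffected sibs."""
    s_pop, s_fam = (
        int(x) for x in np.random.SeedSequence(seed).generate_state(2) % (2**31)
    )
    model = simulate_population(
        2,
        DEFAULT_CHROM_LENGTH,
        DEFAULT_SNPS_PER_CHROM,
        seed=s_pop,
        chrom_names=("14", "15"),
    )
    pedigree, matrix, truth = simulate_backcross(
        model,
        DEFAULT_DELETION,
        DEFAULT_INSERTED_SEQ,
        n_dams=5,
        n_offspring_per_dam=(5, 5, 5, 5, 4),
        seed=s_fam,
        n_carrier_dams=3,
        min_affected=3,
        n_genotyped_cases=3,
        n_genotyped_unaffected=9,
    )
    return model, pedigree, matrix, truth


# ---------------------------------------------------------------------------
# sequencing-evidence generators
# ---------------------------------------------------------------------------


def simulate_depth(
    truth: FamilyTruth,
    sample_id: str,
    region: tuple[str, int, int],
    mean_depth: float = 30.0,
    window_size: int = 1000,
    dispersion: float = 0.1,
    seed: int = 0,
    *,
    focal_radius: int = 2000,
    mismap_floor: float = 0.02,
) -> DepthProfile:
    """Windowed negative-binomial depth, halved over a heterozygous deletion.

    Window means are ``mean_depth * copy_number / 2`` inside the deletion
    (floored at ``mismap_floor * mean_depth`` to mimic mismapped reads) and
    ``mean_depth`` outside; variance is ``mu + dispersion * mu**2``.
    Per-base Poisson tracks cover ``focal_radius`` around each breakpoint.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if sample_id not in truth.carrier_status:
        raise ValueError(f"unknown sample {sample_id!r}")
    chrom, start, end = region
    if start < 1 or end < start:
        raise ValueError("invalid region")
    copies = truth.carrier_status[sample_id]
    del_chrom, del_start, del_end = truth.deletion
    on_del_chrom = chrom == del_chrom
    if on_del_chrom and not (start < del_start and end > del_end):
        raise ValueError("region must cover the deletion plus flanks")

    cn = 2 - copies
    inside_mean = max(mean_depth * cn / 2.0, mismap_floor * mean_depth)

    rng = np.random.default_rng(seed)
    window_starts = np.arange(start, end - window_size + 2, window_size, dtype=np.int64)
    w_end = window_starts + window_size - 1
    if on_del_chrom and copies > 0:
        ov = np.maximum(
            0,
            np.minimum(w_end, del_end) - np.maximum(window_starts, del_start) + 1,
        )
        frac = ov / window_size
    else:
        frac = np.zeros(len(window_starts))
    mu = (1 - frac) * mean_depth + frac * inside_mean

    if dispersion > 0:
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param).astype(np.float64)
    else:
        counts = rng.poisson(mu).astype(np.float64)

    per_base: list[tuple[int, np.ndarray]] = []
    if on_del_chrom:
        for edge in (del_start, del_end):
            lo = max(start, edge - focal_radius)
            hi = min(end, edge + focal_radius)
            bp_pos = np.arange(lo, hi + 1)
            if copies > 0:
                bp_mu = np.where(
                    (bp_pos >= del_start) & (bp_pos <= del_end),
                    inside_mean,
                    mean_depth,
                )
            else:
                bp_mu = np.full(len(bp_pos), mean_depth)
            per_base.append((int(lo), rng.poisson(bp_mu).astype(np.float64)))

    return DepthProfile(chrom, window_size, window_starts, counts, per_base)


def simulate_discordant_pairs(
    truth: FamilyTruth,
    carrier_status: int,
    n_pairs: int,
    nominal_insert_mean: float = 400.0,
    insert_sd: float = 30.0,
    seed: int = 0,
    *,
    read_len: int = 100,
) -> list[ReadPair]:
    """Read pairs straddling the deletion on a carrier's deletion allele.

    On the reference, the apparent insert (inner distance plus both read
    lengths) of such a pair is the fragment length plus the net deleted
    length, which is how the depth caller recognises them.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if carrier_status not in (0, 1, 2):
        raise ValueError("carrier_status must be 0, 1 or 2")
    if carrier_status == 0 or n_pairs == 0:
        return []
    _, del_start, del_end = truth.deletion
    ins_len = len(truth.inserted_seq)
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    min_len = 2 * read_len + ins_len + 1
    for _ in range(n_pairs):
        frag = int(round(rng.normal(nominal_insert_mean, insert_sd)))
        frag = max(frag, min_len)
        gap = frag - 2 * read_len - ins_len  # inner gap on the deletion allele
        a = int(rng.integers(0, gap + 1))  # bases of gap upstream of the junction
        left_end = del_start - 1 - a
        right_start = del_end + 1 + (gap - a)
        pairs.append(ReadPair(left_end, right_start, frag))
    return pairs


def simulate_control_cohort(
    model: PopulationModel,
    n_samples: int,
    site_density: float,
    seed: int,
    private_sites: Optional[set] = None,
) -> pd.DataFrame:
    """A control-cohort site table (chrom, pos, ref, alt).

    Emulates a large reference panel at reduced scale: the returned sites are
    segregating somewhere in the cohort, and are guaranteed disjoint from any
    ``private_sites`` (given as (chrom, pos) or (chrom, pos, ref, alt)
    tuples) so that caller-private variants stay private.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if site_density < 0:
        raise ValueError("site_density must be non-negative")
    excluded: set[tuple[str, int]] = set()
    if private_sites:
        for site in private_sites:
            excluded.add((str(site[0]), int(site[1])))

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, str, str]] = []
    for name, length in model.chromosomes:
        n_sites = int(round(site_density * length))
        if n_sites == 0:
            continue
        pos = _unique_positions(rng, length, n_sites)
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        for p, r, a in zip(pos, ref_idx, alt_idx):
            if (name, int(p)) in excluded:
                continue
            rows.append((name, int(p), str(_BASES[r]), str(_BASES[a])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def simulate_sire_variants(
    model: PopulationModel,
    cohort: pd.DataFrame,
    n_shared: int,
    n_private: int,
    seed: int,
    exclude_intervals: Optional[list[tuple[str, int, int]]] = None,
):
    """Small-variant table for the sequenced sire.

    ``n_shared`` heterozygous sites are re-drawn from the cohort table (so
    cohort subtraction removes them); ``n_private`` heterozygous sites are
    placed at novel positions, avoiding ``exclude_intervals`` — emulating a
    carrier whose candidate region is clean of private small variants.
    """
    from .variant_filtering import VariantRecord

    rng = np.random.default_rng(seed)
    exclude_intervals = exclude_intervals or []
    records: list[VariantRecord] = []

    if n_shared > len(cohort):
        raise ValueError("n_shared exceeds cohort size")
    if n_shared > 0:
        idx = rng.choice(len(cohort), size=n_shared, replace=False)
        for _, row in cohort.iloc[np.sort(idx)].iterrows():
            records.append(
                VariantRecord(row.chrom, int(row.pos), row.ref, row.alt, "het")
            )

    cohort_keys = {(r.chrom, int(r.pos)) for r in cohort.itertuples()}

    def _excluded(chrom: str, pos: int) -> bool:
        return any(
            chrom == c and s <= pos <= e for c, s, e in exclude_intervals
        )

    made = 0
    attempts = 0
    while made < n_private and attempts < 100_000:
        attempts += 1
        ci = int(rng.integers(0, len(model.chromosomes)))
        name, length = model.chromosomes[ci]
        pos = int(rng.integers(1, length + 1))
        if (name, pos) in cohort_keys or _excluded(name, pos):
            continue
        r = int(rng.integers(0, 4))
        a = (r + int(rng.integers(1, 4))) % 4
        records.append(
            VariantRecord(name, pos, str(_BASES[r]), str(_BASES[a]), "het")
        )
        made += 1
    if made < n_private:  # pragma: no cover
        raise RuntimeError("could not place private variants")
    records.sort(key=lambda v: (v.chrom, v.pos))
    return records


def synthetic_gene_model(deletion: tuple[str, int, int]):
    """A synthetic six-exon gene straddling the deletion.

    Proportions mirror an R-spondin-like coding gene: 729 bp of CDS (243 aa)
    of which three internal exons totalling 522 bp (174 aa, 71.6% of the
    protein) fall inside the deletion.  Purely a constructed fixture — real
    exon coordinates are not shipped.
    """
    from .consequence_annotation import GeneModel

    chrom, ds, de = deletion
    if de - ds + 1 < 30_500:
        raise ValueError("deletion too short for the synthetic gene layout")
    exons = (
        (ds - 15_000, ds - 14_901),  # 100 bp, untranslated
        (ds - 12_000, ds - 11_911),  # 90 bp CDS
        (ds + 5_000, ds + 5_173),  # 174 bp CDS, inside deletion
        (ds + 15_000, ds + 15_173),  # 174 bp CDS, inside deletion
        (ds + 30_000, ds + 30_173),  # 174 bp CDS, inside deletion
        (de + 5_000, de + 5_116),  # 117 bp CDS
    )
    cds = exons[1:]
    return GeneModel(
        name="RSPO2-like (synthetic)", chrom=chrom, strand="+", exons=exons, cds=cds
    )
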