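"""Readers and writers for the pipeline's file formats.

Conventions: in-memory coordinates are 1-based fully closed; BED and
bedGraph are converted to/from 0-based half-open at the file boundary.
Genotype matrices travel as PLINK PED/MAP text; tables as TSV; truth and
reports as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .consequence_annotation import GeneModel
from .homozygosity_mapping import CandidateRegion
from .pedigree import Individual, Pedigree
from .segregation_pcr import Primer
from .sv_depth_caller import DeletionCall
from .synthetic_family import (
    DepthProfile,
    FamilyTruth,
    GenotypeMatrix,
    MISSING,
    ReadPair,
)

_SEX_TO_PED = {"M": "1", "F": "2", "U": "0"}
_PED_TO_SEX = {"1": "M", "2": "F"}

# B-allele count -> pair of allele letters
_CALL_TO_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------


def write_ped_map(
    matrix: GenotypeMatrix,
    prefix: str | Path,
    pedigree: Optional[Pedigree] = None,
    family_id: str = "FAM1",
) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for chrom, sid, pos in zip(matrix.chrom, matrix.snp_ids, matrix.pos):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for r, sample in enumerate(matrix.sample_ids):
            if pedigree is not None and sample in pedigree:
                ind = pedigree.get(sample)
                pat = ind.sire_id or "0"
                mat = ind.dam_id or "0"
                sex = _SEX_TO_PED.get(ind.sex, "0")
                pheno = "2" if ind.affected else "1"
            else:
                pat = mat = "0"
                sex = "0"
                pheno = "-9"
            alleles = []
            for call in matrix.calls[r]:
                a, b = _CALL_TO_ALLELES[int(call)]
                alleles.append(f"{a} {b}")
            fh.write(
                f"{family_id} {sample} {pat} {mat} {sex} {pheno} "
                + " ".join(alleles)
                + "\n"
            )


def read_ped_map(prefix: str | Path) -> tuple[GenotypeMatrix, Pedigree]:
    """Read PED/MAP back; parents absent from the file become unknown."""
    prefix = Path(prefix)
    chroms, snp_ids, positions = [], [], []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            c, sid, _, pos = line.split()
            chroms.append(c)
            snp_ids.append(sid)
            positions.append(int(pos))
    rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            rows.append(fields)
    ids_in_file = {f[1] for f in rows}
    sample_ids: list[str] = []
    individuals: list[Individual] = []
    calls = np.empty((len(rows), len(positions)), dtype=np.int8)
    for r, fields in enumerate(rows):
        _, iid, pat, mat, sex, pheno = fields[:6]
        sample_ids.append(iid)
        individuals.append(
            Individual(
                id=iid,
                sire_id=pat if pat != "0" and pat in ids_in_file else None,
                dam_id=mat if mat != "0" and mat in ids_in_file else None,
                sex=_PED_TO_SEX.get(sex, "U"),
                affected=pheno == "2",
                available=True,
            )
        )
        allele_fields = fields[6:]
        if len(allele_fields) != 2 * len(positions):
            raise ValueError(f"PED line {r + 1}: wrong number of allele columns")
        for s in range(len(positions)):
            a, b = allele_fields[2 * s], allele_fields[2 * s + 1]
            if a == "0" or b == "0":
                calls[r, s] = MISSING
            else:
                calls[r, s] = (a == "B") + (b == "B")
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        snp_ids=np.array(snp_ids, dtype=object),
        calls=calls,
    )
    # founders first so pedigree validation (parents precede offspring) holds
    founders = [i for i in individuals if i.sire_id is None and i.dam_id is None]
    others = [i for i in individuals if i not in founders]
    return matrix, Pedigree(founders + others)


# ---------------------------------------------------------------------------
# pedigree / truth / pairs tables
# ---------------------------------------------------------------------------


def write_pedigree_tsv(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire_id\tdam_id\tsex\taffected\tavailable\n")
        for ind in pedigree:
            fh.write(
                f"{ind.id}\t{ind.sire_id or '.'}\t{ind.dam_id or '.'}\t{ind.sex}\t"
                f"{int(ind.affected)}\t{int(ind.available)}\n"
            )


def read_pedigree_tsv(path: str | Path) -> Pedigree:
    individuals = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("pedigree TSV must start with an 'id' header line")
        for line in fh:
            iid, sire, dam, sex, affected, available = line.rstrip("\n").split("\t")
            individuals.append(
                Individual(
                    id=iid,
                    sire_id=None if sire == "." else sire,
                    dam_id=None if dam == "." else dam,
                    sex=sex,
                    affected=affected == "1",
                    available=available == "1",
                )
            )
    return Pedigree(individuals)


def write_truth_json(truth: FamilyTruth, path: str | Path) -> None:
    chrom, start, end = truth.deletion
    payload = {
        "deletion": {"chrom": chrom, "start": start, "end": end},
        "inserted_seq": truth.inserted_seq,
        "carrier_status": truth.carrier_status,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> FamilyTruth:
    payload = json.loads(Path(path).read_text())
    d = payload["deletion"]
    return FamilyTruth(
        deletion=(d["chrom"], int(d["start"]), int(d["end"])),
        inserted_seq=payload["inserted_seq"],
        carrier_status={k: int(v) for k, v in payload["carrier_status"].items()},
    )


def write_pairs_tsv(pairs: Iterable[ReadPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("left_end\tright_start\tnominal_insert\n")
        for p in pairs:
            fh.write(f"{p.left_end}\t{p.right_start}\t{p.nominal_insert}\n")


def read_pairs_tsv(path: str | Path) -> list[ReadPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        ReadPair(int(r.left_end), int(r.right_start), int(r.nominal_insert))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# depth profiles (bedGraph)
# ---------------------------------------------------------------------------


def write_bedgraph(profile: DepthProfile, path: str | Path) -> None:
    """Windowed counts as bedGraph (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for start, count in zip(profile.window_starts, profile.counts):
            fh.write(f"{profile.chrom}\t{start - 1}\t{start - 1 + profile.window_size}\t{count:g}\n")


def read_bedgraph(path: str | Path) -> DepthProfile:
    chroms, starts, counts = [], [], []
    window = None
    with open(path) as fh:
        for line in fh:
            chrom, s0, e0, v = line.split()
            w = int(e0) - int(s0)
            window = w if window is None else window
            if w != window:
                raise ValueError("bedGraph windows are not uniform")
            chroms.append(chrom)
            starts.append(int(s0) + 1)
            counts.append(float(v))
    if not starts:
        raise ValueError("empty bedGraph")
    if len(set(chroms)) != 1:
        raise ValueError("expected a single-chromosome bedGraph")
    return DepthProfile(
        chrom=chroms[0],
        window_size=window,
        window_starts=np.array(starts, dtype=np.int64),
        counts=np.array(counts, dtype=np.float64),
    )


def write_per_base_bedgraph(
    chrom: str, tracks: list[tuple[int, np.ndarray]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for start, counts in tracks:
            for i, v in enumerate(counts):
                pos0 = start - 1 + i
                fh.write(f"{chrom}\t{pos0}\t{pos0 + 1}\t{v:g}\n")


def read_per_base_bedgraph(path: str | Path) -> list[tuple[int, np.ndarray]]:
    """Re-assemble contiguous 1-bp bedGraph records into per-base tracks."""
    tracks: list[tuple[int, list[float]]] = []
    with open(path) as fh:
        for line in fh:
            _, s0, e0, v = line.split()
            pos = int(s0) + 1
            if int(e0) - int(s0) != 1:
                raise ValueError("per-base bedGraph must have 1-bp records")
            if tracks and pos == tracks[-1][0] + len(tracks[-1][1]):
                tracks[-1][1].append(float(v))
            else:
                tracks.append((pos, [float(v)]))
    return [(start, np.array(vals)) for start, vals in tracks]


# ---------------------------------------------------------------------------
# variants / cohort / primers
# ---------------------------------------------------------------------------


def write_variants_tsv(variants, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgenotype\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.genotype}\n")


def read_variants_tsv(path: str | Path):
    from .variant_filtering import VariantRecord

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError("variant TSV must start with a 'chrom' header line")
        for lineno, line in enumerate(fh, start=2):
            try:
                chrom, pos, ref, alt, gt = line.rstrip("\n").split("\t")
                out.append(VariantRecord(chrom, int(pos), ref, alt, gt))
            except ValueError as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {exc}") from exc
    return out


def read_vcf_variants(path: str | Path, sample: int = 0):
    """Read biallelic records from a VCF via cyvcf2.

    Multi-allelic sites must be pre-split (one ALT per record).  Genotype is
    taken from the chosen sample column.
    """
    from cyvcf2 import VCF

    from .variant_filtering import VariantRecord

    out = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "pre-split one alt per record"
            )
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        code = rec.gt_types[sample]
        if code == 2:
            continue
        genotype = {0: "hom_ref", 1: "het", 3: "hom_alt"}[int(code)]
        out.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], genotype))
    return out


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_primers_tsv(path: str | Path) -> list[Primer]:
    """Primers TSV: name, sequence, orientation, five_prime_pos."""
    df = pd.read_csv(path, sep="\t")
    return [
        Primer(
            name=str(r.name_),
            sequence=str(r.sequence),
            orientation=str(r.orientation),
            five_prime_pos=int(r.five_prime_pos),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


# ---------------------------------------------------------------------------
# candidate regions / gene models / deletion calls
# ---------------------------------------------------------------------------


def write_regions_bed(regions: list[CandidateRegion], path: str | Path) -> None:
    """Candidate regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion{i + 1}\t{r.n_snps}\n")


def write_regions_tsv(regions: list[CandidateRegion], path: str | Path) -> None:
    """Haplotype signatures: one row per region SNP with the shared call."""
    with open(path, "w") as fh:
        fh.write("region\tchrom\tstart\tend\tsnp_id\tshared_call\n")
        for i, r in enumerate(regions):
            for sid, call in zip(r.snp_ids, r.case_haplotype):
                fh.write(
                    f"region{i + 1}\t{r.chrom}\t{r.start}\t{r.end}\t{sid}\t{int(call)}\n"
                )


def read_gene_model_bed12(path: str | Path) -> GeneModel:
    """One-transcript BED12 -> GeneModel (thickStart/thickEnd bound the CDS)."""
    line = Path(path).read_text().strip().splitlines()[0]
    f = line.split("\t")
    if len(f) < 12:
        raise ValueError("BED12 requires 12 columns")
    chrom, chrom_start = f[0], int(f[1])
    name, strand = f[3], f[5]
    thick_start, thick_end = int(f[6]), int(f[7])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = []
    for size, off in zip(sizes, offsets):
        s0 = chrom_start + off
        exons.append((s0 + 1, s0 + size))  # to 1-based closed
    cds = []
    for es, ee in exons:
        cs = max(es, thick_start + 1)
        ce = min(ee, thick_end)
        if cs <= ce:
            cds.append((cs, ce))
    return GeneModel(
        name=name, chrom=chrom, strand=strand, exons=tuple(exons), cds=tuple(cds)
    )


def write_deletion_vcf(
    call: DeletionCall, path: str | Path, sample: str = "sire"
) -> None:
    """Symbolic-ALT VCF record for a deletion (or delins) call."""
    gt = {"+/+": "0/0", "+/-": "0/1", "-/-": "1/1"}[call.genotype]
    info = f"SVTYPE=DEL;END={call.end};SVLEN=-{call.length}"
    if call.inserted_seq:
        info += f";SVINSSEQ={call.inserted_seq}"
    info += f";PAIRSUPPORT={call.pair_support}"
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="Inserted sequence">',
        '##INFO=<ID=PAIRSUPPORT,Number=1,Type=Integer,Description="Discordant pairs">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
        f"{call.chrom}\t{call.start}\t.\tN\t<DEL>\t.\tPASS\t{info}\tGT\t{gt}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
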