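"""End-to-end orchestration: QC -> ROH mapping -> pedigree filter -> variant
triage -> (if the candidate region is clean of small variants) depth-based SV
calling -> PCR segregation -> coding annotation.

The escalation branch is explicit: structural-variant calling runs only when
no private small variant survives inside the candidate region, reproducing
the decision structure of a mapping study that finds its candidate interval
empty of SNPs and indels.  Every stage writes its counts into a single
serializable :class:`MappingReport`.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as rio
from .consequence_annotation import coding_impact, hgvs_name, overlap_exons
from .genotype_qc import qc_filter
from .homozygosity_mapping import (
    RohParams,
    detect_roh_sample,
    filter_regions_by_support,
    merge_candidate_regions,
    pedigree_filter,
    shared_case_regions,
)
from .segregation_pcr import (
    AlleleModel,
    Edit,
    Primer,
    cosegregation_check,
    genotype_by_pcr,
    population_screen,
    segregation_ratio_test,
)
from .sv_depth_caller import call_deletion
from .synthetic_family import (
    DEFAULT_CHROM_LENGTH,
    DEFAULT_DELETION,
    DEFAULT_INSERTED_SEQ,
    DEFAULT_SNPS_PER_CHROM,
    simulate_backcross,
    simulate_control_cohort,
    simulate_depth,
    simulate_discordant_pairs,
    simulate_population,
    simulate_sire_variants,
    synthetic_gene_model,
)
from .variant_filtering import (
    VariantRecord,
    restrict_to_intervals,
    select_heterozygous,
    subtract_cohort,
)

_BASES = "ACGT"

STAGES = ("qc", "roh", "variants", "sv", "pcr", "annotation")

# assay geometry relative to the called deletion: forward primer 575 bp
# upstream of the left breakpoint, wild-type reverse primer 394 bp inside,
# mutant-specific reverse primer 161 bp downstream of the right breakpoint
_F_OFFSET = 575
_WT_R_OFFSET = 394
_MT_R_OFFSET = 161
_PRIMER_LEN = 20


@dataclass
class SimulationConfig:
    """Study conditions for the simulated family (defaults mirror the
    default backcross: 5 dams, 24 calves, ~50-kb deletion, 30x sire)."""

    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = DEFAULT_CHROM_LENGTH
    n_snps_per_chrom: int = DEFAULT_SNPS_PER_CHROM
    chrom_names: tuple[str, ...] = ("14", "15")
    deletion: tuple[str, int, int] = DEFAULT_DELETION
    inserted_seq: str = DEFAULT_INSERTED_SEQ
    n_dams: int = 5
    n_offspring_per_dam: tuple[int, ...] = (5, 5, 5, 5, 4)
    n_carrier_dams: int = 3
    min_affected: int = 3
    n_genotyped_cases: int = 3
    n_genotyped_unaffected: int = 9
    error_rate: float = 0.002
    missing_rate: float = 0.01
    mean_depth: float = 30.0
    window_size: int = 1000
    dispersion: float = 0.1
    depth_flank_bp: int = 100_000
    focal_radius: int = 16_000
    breakpoint_search_radius: int = 8000
    n_pairs: int = 20
    nominal_insert_mean: float = 400.0
    insert_sd: float = 30.0
    n_control_samples: int = 100
    control_site_density: float = 2e-5
    n_shared_variants: int = 200
    n_private_variants: int = 30
    n_private_in_region: int = 0  # force small variants into the candidate region
    n_population_screen: int = 182


@dataclass
class PipelineConfig:
    simulation: Optional[SimulationConfig] = None
    inputs: dict = field(default_factory=dict)  # file paths for non-simulated runs
    stages: tuple[str, ...] = STAGES
    qc_min_call_rate: float = 0.90
    qc_min_maf: float = 0.01
    roh: RohParams = field(default_factory=RohParams)
    merge_gap_bp: int = 1_000_000
    min_region_snps: int = 30
    out_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        sim = payload.pop("simulation", None)
        roh = payload.pop("roh", None)
        cfg = cls(**payload)
        if sim is not None:
            sim = dict(sim)
            for key in ("chrom_names", "n_offspring_per_dam", "deletion"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        if roh is not None:
            cfg.roh = RohParams(**roh)
        if "stages" in payload or isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        return _canonical(dataclasses.asdict(self))


def _np_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _canonical(obj):
    """JSON-canonical form: tuples become lists, numpy scalars plain."""
    return json.loads(json.dumps(obj, default=_np_default))


@dataclass
class MappingReport:
    """All stage outputs, parameters and seeds of one pipeline run."""

    config: dict
    stages: dict

    def to_dict(self) -> dict:
        return _canonical({"config": self.config, "stages": self.stages})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "MappingReport":
        payload = json.loads(Path(path).read_text())
        return cls(config=payload["config"], stages=payload["stages"])

    def summary_text(self) -> str:
        lines = []
        for stage in STAGES:
            if stage not in self.stages:
                continue
            info = self.stages[stage]
            if "skipped" in info:
                lines.append(f"[{stage}] skipped: {info['skipped']}")
                continue
            keys = {
                "qc": ("n_input_snps", "n_retained"),
                "roh": ("n_shared_regions", "n_after_pedigree_filter", "n_candidate_regions"),
                "variants": ("n_het", "n_after_cohort", "n_in_candidate_region"),
                "sv": ("hgvs", "genotype", "pair_support"),
                "pcr": ("cosegregation_perfect", "segregation_p_value", "population_carriers"),
                "annotation": ("n_exons_deleted", "aa_deleted", "protein_percent"),
            }[stage]
            parts = [f"{k}={info.get(k)}" for k in keys if k in info]
            lines.append(f"[{stage}] " + " ".join(parts))
        return "\n".join(lines)


def _random_primer_seq(rng: np.random.Generator, length: int = _PRIMER_LEN) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _simulate_inputs(sim: SimulationConfig) -> dict:
    """Generate every pipeline input from the simulation config."""
    seeds = np.random.SeedSequence(sim.seed).generate_state(8) % (2**31)
    s_pop, s_fam, s_depth, s_pairs, s_cohort, s_var, s_reg, s_primer = (
        int(x) for x in seeds
    )
    model = simulate_population(
        sim.n_chroms,
        sim.chrom_length,
        sim.n_snps_per_chrom,
        seed=s_pop,
        chrom_names=sim.chrom_names,
    )
    pedigree, matrix, truth = simulate_backcross(
        model,
        sim.deletion,
        sim.inserted_seq,
        n_dams=sim.n_dams,
        n_offspring_per_dam=sim.n_offspring_per_dam,
        seed=s_fam,
        error_rate=sim.error_rate,
        missing_rate=sim.missing_rate,
        n_carrier_dams=sim.n_carrier_dams,
        min_affected=sim.min_affected,
        n_genotyped_cases=sim.n_genotyped_cases,
        n_genotyped_unaffected=sim.n_genotyped_unaffected,
    )
    chrom, ds, de = sim.deletion
    region = (chrom, ds - sim.depth_flank_bp, de + sim.depth_flank_bp // 2)
    depth = simulate_depth(
        truth,
        "sire",
        region,
        mean_depth=sim.mean_depth,
        window_size=sim.window_size,
        dispersion=sim.dispersion,
        seed=s_depth,
        focal_radius=sim.focal_radius,
    )
    pairs = simulate_discordant_pairs(
        truth,
        truth.carrier_status["sire"],
        sim.n_pairs,
        sim.nominal_insert_mean,
        sim.insert_sd,
        seed=s_pairs,
    )
    cohort = simulate_control_cohort(
        model, sim.n_control_samples, sim.control_site_density, seed=s_cohort
    )
    # private small variants stay off the mapped chromosome so the candidate
    # region is clean and the SV escalation branch is exercised
    sire_variants = simulate_sire_variants(
        model,
        cohort,
        sim.n_shared_variants,
        sim.n_private_variants,
        seed=s_var,
        exclude_intervals=[(chrom, 1, model.chrom_length(chrom))],
    )
    if sim.n_private_in_region > 0:
        rng = np.random.default_rng(s_reg)
        cohort_keys = {(r.chrom, int(r.pos)) for r in cohort.itertuples()}
        placed = 0
        while placed < sim.n_private_in_region:
            pos = int(rng.integers(ds - 20_000, de + 20_000))
            if (chrom, pos) in cohort_keys:
                continue
            r = int(rng.integers(0, 4))
            a = (r + int(rng.integers(1, 4))) % 4
            sire_variants.append(
                VariantRecord(chrom, pos, _BASES[r], _BASES[a], "het")
            )
            placed += 1
        sire_variants.sort(key=lambda v: (v.chrom, v.pos))
    rng = np.random.default_rng(s_primer)
    primer_seqs = [_random_primer_seq(rng) for _ in range(3)]
    return {
        "model": model,
        "pedigree": pedigree,
        "matrix": matrix,
        "truth": truth,
        "depth": depth,
        "pairs": pairs,
        "cohort": cohort,
        "sire_variants": sire_variants,
        "gene_model": synthetic_gene_model(sim.deletion),
        "primer_seqs": primer_seqs,
    }


_STAGE_INPUTS = {
    "qc": ["genotypes"],
    "roh": ["genotypes", "pedigree"],
    "variants": ["sire_variants", "cohort"],
    "sv": ["depth"],
    "pcr": ["truth", "pedigree"],
    "annotation": ["gene_model"],
}


def _load_inputs(config: PipelineConfig) -> dict:
    paths = config.inputs
    for stage in config.stages:
        missing = [k for k in _STAGE_INPUTS[stage] if k not in paths]
        if missing:
            raise ValueError(
                f"stage {stage!r} selected but inputs missing: {', '.join(missing)}"
            )
    data: dict = {}
    if "genotypes" in paths:
        matrix, ped_from_file = rio.read_ped_map(paths["genotypes"])
        data["matrix"] = matrix
        data["pedigree"] = ped_from_file
    if "pedigree" in paths:
        data["pedigree"] = rio.read_pedigree_tsv(paths["pedigree"])
    if "sire_variants" in paths:
        p = str(paths["sire_variants"])
        data["sire_variants"] = (
            rio.read_vcf_variants(p) if p.endswith(".vcf") else rio.read_variants_tsv(p)
        )
    if "cohort" in paths:
        data["cohort"] = rio.read_cohort_tsv(paths["cohort"])
    if "depth" in paths:
        data["depth"] = rio.read_bedgraph(paths["depth"])
        if "depth_per_base" in paths:
            data["depth"].per_base = rio.read_per_base_bedgraph(paths["depth_per_base"])
    if "pairs" in paths:
        data["pairs"] = rio.read_pairs_tsv(paths["pairs"])
    if "truth" in paths:
        data["truth"] = rio.read_truth_json(paths["truth"])
    if "gene_model" in paths:
        data["gene_model"] = rio.read_gene_model_bed12(paths["gene_model"])
    data.setdefault("pairs", [])
    return data


def run_pipeline(config: PipelineConfig) -> MappingReport:
    """Run the selected stages in order and return the structured report."""
    unknown = [s for s in config.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if config.simulation is not None:
        data = _simulate_inputs(config.simulation)
    else:
        data = _load_inputs(config)

    stages: dict = {}
    report = MappingReport(config=config.to_dict(), stages=stages)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    matrix = data.get("matrix")
    pedigree = data.get("pedigree")
    truth = data.get("truth")

    # ------------------------------------------------------------------ qc
    if "qc" in config.stages:
        matrix, qc_report = qc_filter(
            matrix, config.qc_min_call_rate, config.qc_min_maf
        )
        stages["qc"] = qc_report.to_dict()
        if out_dir:
            rio.write_ped_map(matrix, out_dir / "filtered", pedigree)

    # ----------------------------------------------------------------- roh
    candidate_regions = []
    if "roh" in config.stages:
        case_ids = [i for i in pedigree.affected_ids() if i in matrix.sample_ids]
        if not case_ids:
            raise ValueError("no genotyped affected individuals for ROH mapping")
        roh_by_case = {c: detect_roh_sample(matrix, c, config.roh) for c in case_ids}
        shared = shared_case_regions(matrix, case_ids, config.roh, roh_by_case)
        surviving = pedigree_filter(shared, matrix, pedigree)
        candidate_regions = filter_regions_by_support(
            merge_candidate_regions(surviving, config.merge_gap_bp),
            config.min_region_snps,
        )
        stages["roh"] = {
            "n_cases": len(case_ids),
            "n_roh_per_case": {c: len(roh_by_case[c]) for c in case_ids},
            "n_shared_regions": len(shared),
            "n_after_pedigree_filter": len(surviving),
            "n_candidate_regions": len(candidate_regions),
            "regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end, "n_snps": r.n_snps}
                for r in candidate_regions
            ],
        }
        if out_dir:
            rio.write_regions_bed(candidate_regions, out_dir / "candidate_regions.bed")
            rio.write_regions_tsv(candidate_regions, out_dir / "candidate_regions.tsv")

    # ------------------------------------------------------------ variants
    escalate = True
    if "variants" in config.stages:
        sire_variants = data["sire_variants"]
        het = select_heterozygous(sire_variants)
        private = subtract_cohort(het, data["cohort"])
        intervals = [(r.chrom, r.start, r.end) for r in candidate_regions]
        in_region = (
            restrict_to_intervals(private, intervals) if intervals else private
        )
        escalate = len(in_region) == 0
        stages["variants"] = {
            "n_input": len(sire_variants),
            "n_het": len(het),
            "n_after_cohort": len(private),
            "n_in_candidate_region": len(in_region),
            "escalate_to_sv": escalate,
            "note": (
                "no private small variant in the candidate region; "
                "proceeding to structural-variant analysis"
                if escalate
                else "private small variants remain in the candidate region"
            ),
        }
        if out_dir:
            rio.write_variants_tsv(in_region, out_dir / "candidate_variants.tsv")

    # ---------------------------------------------------------------- sv
    call = None
    if "sv" in config.stages:
        if not escalate:
            stages["sv"] = {
                "skipped": "small variants remain in the candidate region; "
                "depth-based SV calling not triggered"
            }
        else:
            sim = config.simulation
            call = call_deletion(
                data["depth"],
                data.get("pairs", []),
                inserted_seq=truth.inserted_seq if truth else "",
                search_radius=(
                    sim.breakpoint_search_radius if sim else 2000
                ),
                nominal_insert_mean=(
                    sim.nominal_insert_mean if sim else 400.0
                ),
                insert_sd=sim.insert_sd if sim else 30.0,
            )
            in_candidate = any(
                r.contains_interval(call.chrom, call.start, call.end)
                for r in candidate_regions
            )
            stages["sv"] = {
                "chrom": call.chrom,
                "start": call.start,
                "end": call.end,
                "length": call.length,
                "hgvs": hgvs_name(call),
                "genotype": call.genotype,
                "depth_ratio": call.depth_ratio,
                "pair_support": call.pair_support,
                "inside_candidate_region": in_candidate,
                "coverage_tests": call.report.to_dict(),
            }
            if out_dir:
                rio.write_deletion_vcf(call, out_dir / "deletion.vcf")

    # ---------------------------------------------------------------- pcr
    if "pcr" in config.stages:
        if call is None:
            stages["pcr"] = {"skipped": "no deletion call to design the assay around"}
        else:
            seqs = data.get("primer_seqs", ["A" * _PRIMER_LEN] * 3)
            fwd = Primer("Del_F", seqs[0], "forward", call.start - _F_OFFSET)
            wt_rev = Primer("DelWt_R", seqs[1], "reverse", call.start + _WT_R_OFFSET)
            mt_rev = Primer("DelMt_R", seqs[2], "reverse", call.end + _MT_R_OFFSET)
            del_chrom, ds, de = truth.deletion
            del_allele = AlleleModel((Edit(ds, de, truth.inserted_seq),))
            genotypes = {
                ind.id: genotype_by_pcr(
                    truth.carrier_status[ind.id], fwd, wt_rev, mt_rev, del_allele
                )
                for ind in pedigree
                if ind.available or ind.affected
            }
            coseg = cosegregation_check(genotypes, pedigree)
            dam_carrier = {
                did: genotypes[did] != "+/+"
                for did in sorted(pedigree.obligate_carrier_dams() | set())
                if did in genotypes
            }
            # include genotyped non-obligate dams so all matings count
            for ind in pedigree:
                if ind.id in genotypes and pedigree.offspring_of(ind.id) and ind.sex == "F":
                    dam_carrier.setdefault(ind.id, genotypes[ind.id] != "+/+")
            seg = segregation_ratio_test(pedigree, dam_carrier)
            n_screen = (
                config.simulation.n_population_screen if config.simulation else 0
            )
            screen_genotypes = [
                genotype_by_pcr(0, fwd, wt_rev, mt_rev, del_allele)
                for _ in range(n_screen)
            ]
            stages["pcr"] = {
                "wt_product_bp": (call.start + _WT_R_OFFSET)
                - (call.start - _F_OFFSET)
                + 1,
                "genotypes": genotypes,
                "cosegregation_perfect": coseg.perfect,
                "violations": coseg.violations,
                "segregation_n": seg.n_offspring,
                "segregation_affected": seg.n_affected,
                "segregation_p_value": seg.p_value,
                "population_screened": n_screen,
                "population_carriers": population_screen(screen_genotypes),
            }

    # --------------------------------------------------------- annotation
    if "annotation" in config.stages:
        if call is None:
            stages["annotation"] = {"skipped": "no deletion call to annotate"}
        else:
            gene = data["gene_model"]
            deletion = (call.chrom, call.start, call.end)
            exons = overlap_exons(deletion, gene)
            impact = coding_impact(deletion, gene)
            stages["annotation"] = {
                "gene": gene.name,
                "exons_deleted": [e.number for e in exons],
                "partial_exons": [e.number for e in exons if e.partial],
                **impact.to_dict(),
            }

    if out_dir:
        report.to_json(out_dir / "mapping_report.json")
    return report
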