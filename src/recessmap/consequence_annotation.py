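"""Coding-consequence annotation of a deletion against a gene model.

Reports which exons a deletion removes, how much coding sequence and how
many amino acids are lost, the fraction of the protein affected, and an
HGVS-style genomic name for the variant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence


def _check_sorted_nonoverlap(ivals: Sequence[tuple[int, int]], what: str) -> None:
    prev_end = 0
    for s, e in ivals:
        if s > e or s < 1:
            raise ValueError(f"invalid {what} interval ({s}, {e})")
        if s <= prev_end:
            raise ValueError(f"{what} intervals must be sorted and non-overlapping")
        prev_end = e


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one transcript; coordinates reference-forward,
    1-based inclusive.  Exon *numbering* follows transcript (strand) order."""

    name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        _check_sorted_nonoverlap(self.exons, "exon")
        _check_sorted_nonoverlap(self.cds, "CDS")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError("every CDS interval must lie within an exon")
        if self.total_cds_bp % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")

    @property
    def total_cds_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def total_aa(self) -> int:
        return self.total_cds_bp // 3

    def exon_number(self, index: int) -> int:
        """1-based transcript-order exon number for reference-order index."""
        if self.strand == "+":
            return index + 1
        return len(self.exons) - index


@dataclass(frozen=True)
class ExonOverlap:
    number: int  # transcript-order exon number, 1-based
    partial: bool  # True when the deletion removes only part of the exon


def overlap_exons(
    deletion: tuple[str, int, int],
    model: GeneModel,
) -> list[ExonOverlap]:
    """Exons overlapped by the deletion, in transcript order.

    A chromosome mismatch yields an empty list with a warning rather than an
    error, so genome-wide sweeps degrade gracefully.
    """
    chrom, dstart, dend = deletion
    if dstart > dend:
        raise ValueError("invalid deletion interval")
    if chrom != model.chrom:
        warnings.warn(
            f"deletion on {chrom} does not touch {model.name} on {model.chrom}",
            stacklevel=2,
        )
        return []
    hits: list[ExonOverlap] = []
    for i, (es, ee) in enumerate(model.exons):
        if es <= dend and dstart <= ee:
            partial = not (dstart <= es and ee <= dend)
            hits.append(ExonOverlap(number=model.exon_number(i), partial=partial))
    hits.sort(key=lambda h: h.number)
    return hits


@dataclass(frozen=True)
class ImpactReport:
    n_exons_deleted: int
    cds_bp_deleted: int
    aa_deleted: int
    total_aa: int
    in_frame: bool

    @property
    def protein_fraction(self) -> float:
        return self.aa_deleted / self.total_aa

    @property
    def protein_percent(self) -> float:
        """Fraction of the protein affected, rounded to one decimal."""
        return round(100.0 * self.protein_fraction, 1)

    def to_dict(self) -> dict:
        return {
            "n_exons_deleted": self.n_exons_deleted,
            "cds_bp_deleted": self.cds_bp_deleted,
            "aa_deleted": self.aa_deleted,
            "total_aa": self.total_aa,
            "protein_percent": self.protein_percent,
            "in_frame": self.in_frame,
        }


def coding_impact(deletion: tuple[str, int, int], model: GeneModel) -> ImpactReport:
    """Coding loss caused by the deletion.

    ``aa_deleted`` is the deleted CDS length / 3 (floored); when the deleted
    CDS length is not a multiple of 3 the variant is flagged out of frame.
    """
    if model.total_cds_bp == 0:
        raise ValueError("gene model has a zero-length CDS")
    chrom, dstart, dend = deletion
    exon_hits = overlap_exons(deletion, model)
    cds_deleted = 0
    if chrom == model.chrom:
        for cs, ce in model.cds:
            cds_deleted += max(0, min(ce, dend) - max(cs, dstart) + 1)
    in_frame = cds_deleted % 3 == 0
    return ImpactReport(
        n_exons_deleted=len(exon_hits),
        cds_bp_deleted=cds_deleted,
        aa_deleted=cds_deleted // 3,
        total_aa=model.total_aa,
        in_frame=in_frame,
    )


def hgvs_name(call) -> str:
    """HGVS-style genomic name: ``g.{start}_{end}del[ins{SEQ}]``.

    Accepts anything with ``start``, ``end`` and ``inserted_seq`` attributes
    (e.g. a depth-caller DeletionCall).  Machine output never carries
    thousands separators.
    """
    if call is None:
        raise ValueError("empty deletion call")
    start, end = call.start, call.end
    if start > end:
        raise ValueError("start must not exceed end")
    ins = call.inserted_seq or ""
    if ins:
        return f"g.{start}_{end}delins{ins}"
    return f"g.{start}_{end}del"
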