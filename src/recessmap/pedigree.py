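"""Pedigree representation for recessive-trait families.

Individuals are listed parents-before-offspring; an affected individual must
have both parents recorded, because the downstream filters (obligate-carrier
dam exclusion, co-segregation checks) rely on parent links being present.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``available`` marks whether a DNA sample exists, i.e. whether the
    individual can appear in a genotype matrix.
    """

    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: str = "U"  # 'M', 'F' or 'U'
    affected: bool = False
    available: bool = True


class Pedigree:
    """An ordered, validated collection of :class:`Individual`.

    Validation enforces: unique ids, parents precede offspring (which also
    rules out cycles), and both parents recorded for every affected
    individual.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in self._by_id:
                    raise ValueError(
                        f"parent {pid!r} of {ind.id!r} must precede it in the pedigree"
                    )
            if ind.affected and (ind.sire_id is None or ind.dam_id is None):
                raise ValueError(
                    f"affected individual {ind.id!r} must have both parents recorded"
                )
            self._by_id[ind.id] = ind

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def get(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def affected_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.affected]

    def obligate_carrier_dams(self) -> set[str]:
        """Dams of affected individuals: must carry one recessive allele."""
        return {
            i.dam_id for i in self.individuals if i.affected and i.dam_id is not None
        }

    def obligate_carrier_sires(self) -> set[str]:
        return {
            i.sire_id for i in self.individuals if i.affected and i.sire_id is not None
        }

    def unaffected_sibs_of_affected(self) -> set[str]:
        """Unaffected individuals sharing at least one parent with a case.

        Parents of cases themselves (the obligate carriers) are excluded even
        when they happen to be half-sibs of the cases, as in a backcross.
        """
        parents_of_cases = self.obligate_carrier_dams() | self.obligate_carrier_sires()
        sibs: set[str] = set()
        for ind in self.individuals:
            if ind.affected or ind.id in parents_of_cases:
                continue
            for case in self.individuals:
                if not case.affected:
                    continue
                share_sire = ind.sire_id is not None and ind.sire_id == case.sire_id
                share_dam = ind.dam_id is not None and ind.dam_id == case.dam_id
                if share_sire or share_dam:
                    sibs.add(ind.id)
                    break
        return sibs

    def offspring_of(self, parent_id: str) -> list[Individual]:
        return [
            i
            for i in self.individuals
            if parent_id in (i.sire_id, i.dam_id)
        ]
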