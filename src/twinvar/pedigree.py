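"""Pedigree representation and PED parsing for a discordant-twin family.

The family model is a nuclear pedigree: two genotyped founder parents, any
number of unaffected siblings, and one monozygotic twin pair of which exactly
one member is affected.  Family size is not fixed to the eight-member study
design; any pedigree satisfying those constraints is accepted.

PLINK-style 6-column PED input (family, individual, father, mother, sex,
phenotype); phenotype coding 2 = affected, 1 = unaffected, 0/-9 = unknown
(treated as unaffected for model logic, flagged).  PED has no twin field, so
the twin pair is supplied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union


class PedigreeError(ValueError):
    """A pedigree invariant is violated; the message names the failing rule."""


@dataclass(frozen=True)
class Member:
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # male / female / unknown
    affected: bool
    affected_known: bool = True


@dataclass(frozen=True)
class Pedigree:
    """Validated family structure with a designated discordant twin pair.

    Invariants (enforced at construction): exactly one affected member, who is
    one of the twins; both twins share the same declared parents; founders
    have absent parent ids; all parent references resolve.
    """

    members: Tuple[Member, ...]
    twin_pair: Tuple[str, str]  # (affected_twin_id, unaffected_twin_id)

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate sample ids in pedigree")
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in by_id:
                    raise PedigreeError(
                        f"parent {pid!r} of {m.sample_id!r} not in family"
                    )
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(
                    f"member {m.sample_id!r} has exactly one declared parent"
                )
        affected = [m.sample_id for m in self.members if m.affected]
        if len(affected) == 0:
            raise PedigreeError("no affected member in pedigree")
        if len(affected) > 1:
            raise PedigreeError(f"{len(affected)} affected members; expected one")
        aff_twin, unaff_twin = self.twin_pair
        for t in self.twin_pair:
            if t not in by_id:
                raise PedigreeError(f"twin {t!r} not in family")
        if by_id[aff_twin].father_id is None:
            raise PedigreeError(f"twin {aff_twin!r} is a founder")
        if by_id[unaff_twin].father_id is None:
            raise PedigreeError(f"twin {unaff_twin!r} is a founder")
        if affected[0] != aff_twin:
            raise PedigreeError(
                f"affected member {affected[0]!r} is not the designated "
                f"affected twin {aff_twin!r}"
            )
        if by_id[unaff_twin].affected:
            raise PedigreeError("both twins are affected; twins must be discordant")
        if (by_id[aff_twin].father_id, by_id[aff_twin].mother_id) != (
            by_id[unaff_twin].father_id,
            by_id[unaff_twin].mother_id,
        ):
            raise PedigreeError("twins do not share the same declared parents")

    # -- derived roles -------------------------------------------------------

    @property
    def affected_twin(self) -> str:
        return self.twin_pair[0]

    @property
    def unaffected_twin(self) -> str:
        return self.twin_pair[1]

    @property
    def father(self) -> str:
        by_id = {m.sample_id: m for m in self.members}
        return by_id[self.affected_twin].father_id  # type: ignore[return-value]

    @property
    def mother(self) -> str:
        by_id = {m.sample_id: m for m in self.members}
        return by_id[self.affected_twin].mother_id  # type: ignore[return-value]

    @property
    def parents(self) -> Tuple[str, str]:
        return (self.father, self.mother)

    @property
    def siblings(self) -> Tuple[str, ...]:
        """Non-twin offspring, in member order."""
        twin_set = set(self.twin_pair)
        parent_set = set(self.parents)
        return tuple(
            m.sample_id
            for m in self.members
            if m.sample_id not in twin_set and m.sample_id not in parent_set
        )

    @property
    def sample_ids(self) -> Tuple[str, ...]:
        return tuple(m.sample_id for m in self.members)

    @property
    def unknown_phenotype_ids(self) -> Tuple[str, ...]:
        return tuple(m.sample_id for m in self.members if not m.affected_known)

    def roles(self) -> Dict[str, str]:
        """Map sample id -> role label (father/mother/sibling/affected_twin/
        unaffected_twin); partitions the family exactly."""
        out = {self.father: "father", self.mother: "mother"}
        out[self.affected_twin] = "affected_twin"
        out[self.unaffected_twin] = "unaffected_twin"
        for s in self.siblings:
            out[s] = "sibling"
        return out


_SEX = {"1": "male", "2": "female"}


def read_pedigree(
    ped_source: Union[str, Path],
    twin_pair: Tuple[str, str],
) -> Pedigree:
    """Parse a 6-column PED file and validate it against the family model.

    Parameters
    ----------
    ped_source : path to a PLINK-style PED file (whitespace-delimited).
    twin_pair : (affected_twin_id, unaffected_twin_id).

    Raises
    ------
    PedigreeError
        On any violated invariant, naming the failing rule.
    """
    members: List[Member] = []
    text = Path(ped_source).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"PED line {lineno}: expected 6 columns, got {len(fields)}"
            )
        _fam, iid, fid, mid, sex, pheno = fields[:6]
        members.append(
            Member(
                sample_id=iid,
                father_id=None if fid in ("0", "") else fid,
                mother_id=None if mid in ("0", "") else mid,
                sex=_SEX.get(sex, "unknown"),
                affected=(pheno == "2"),
                affected_known=(pheno in ("1", "2")),
            )
        )
    if not members:
        raise PedigreeError(f"empty PED file: {ped_source}")
    return Pedigree(members=tuple(members), twin_pair=tuple(twin_pair))


def write_pedigree(ped: Pedigree, destination: Union[str, Path]) -> None:
    """Write a Pedigree back to 6-column PED (family id ``FAM1``)."""
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    lines = []
    for m in ped.members:
        lines.append(
            "\t".join(
                [
                    "FAM1",
                    m.sample_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    sex_code[m.sex],
                    "2" if m.affected else ("1" if m.affected_known else "0"),
                ]
            )
        )
    Path(destination).write_text("\n".join(lines) + "\n")
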