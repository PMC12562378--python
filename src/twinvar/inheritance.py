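"""Family genotype-model screens and twin-concordance analysis.

Four screens over a discordant-twin pedigree:

* **de novo** — alt present in the affected twin (het or hom_alt; a 1/1 call
  still flags a variant absent from everyone else) and hom_ref in every other
  member.
* **autosomal recessive** — affected twin hom_alt, both parents het carriers,
  and neither the unaffected twin nor any sibling hom_alt.
* **autosomal dominant** — affected twin het, all other members hom_ref;
  with incomplete penetrance enabled, exactly one het parent is tolerated
  (and noted).
* **homozygous screen** — affected twin hom_alt, no constraint on the rest;
  comparison against the unaffected twin happens at report time.

No-call handling is a policy: under ``permissive`` (default) a ./. genotype
in a member whose required class is hom_ref counts as compatible but attaches
a ``no_call_supported`` note, so weakly supported candidates survive to
evidence review instead of silently disappearing; under ``strict`` any
required member with a no-call excludes the variant.  The affected twin's own
genotype must always be an actual call of the required class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from twinvar.core import AnnotatedVariant, GenotypeClass, is_autosome
from twinvar.pedigree import Pedigree

NOTE_NO_CALL = "no_call_supported"
NOTE_PENETRANCE = "penetrance_exception"
NOTE_CONCORDANT_TWIN = "concordant_twin"


@dataclass(frozen=True)
class ModelConfig:
    no_call_policy: str = "permissive"  # or "strict"
    incomplete_penetrance: bool = False
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if self.no_call_policy not in ("permissive", "strict"):
            raise ValueError(f"unknown no_call_policy {self.no_call_policy!r}")


@dataclass(frozen=True)
class ScreenResult:
    admitted: bool
    notes: FrozenSet[str] = frozenset()

    def __bool__(self) -> bool:
        return self.admitted


@dataclass(frozen=True)
class ModelCandidate:
    """A variant admitted by one genotype-model screen."""

    variant: AnnotatedVariant
    model: str  # de_novo / autosomal_recessive / autosomal_dominant / homozygous_screen
    support_notes: FrozenSet[str] = frozenset()


@dataclass(frozen=True)
class ConcordanceSummary:
    """Twin variant-sharing tallies; percent_shared = 100*shared/(shared+
    unique_a+unique_b), 0 when no variant is present in either twin."""

    shared_count: int
    unique_to_affected: int
    unique_to_unaffected: int

    @property
    def percent_shared(self) -> float:
        denom = self.shared_count + self.unique_to_affected + self.unique_to_unaffected
        if denom == 0:
            return 0.0
        return 100.0 * self.shared_count / denom


_REJECT = ScreenResult(False)


def _classes(v: AnnotatedVariant, ped: Pedigree) -> Dict[str, GenotypeClass]:
    """Genotype class per pedigree member; missing member -> hard error."""
    return {sid: v.genotype_class(sid) for sid in ped.sample_ids}


def _autosome_gate(v: AnnotatedVariant, cfg: ModelConfig) -> bool:
    return (not cfg.autosomes_only) or is_autosome(v.key.chrom)


def _require_hom_ref(
    cls: GenotypeClass, cfg: ModelConfig, notes: set
) -> bool:
    """Member required to be hom_ref; no_call compatible only when permissive."""
    if cls == GenotypeClass.HOM_REF:
        return True
    if cls == GenotypeClass.NO_CALL and cfg.no_call_policy == "permissive":
        notes.add(NOTE_NO_CALL)
        return True
    return False


def de_novo_screen(
    v: AnnotatedVariant, ped: Pedigree, cfg: ModelConfig = ModelConfig()
) -> ScreenResult:
    """Alt in the affected twin only: every other member hom_ref (or no-call
    under the permissive policy, noted)."""
    if not _autosome_gate(v, cfg):
        return _REJECT
    cls = _classes(v, ped)
    if cls[ped.affected_twin] not in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
        return _REJECT
    notes: set = set()
    for sid in ped.sample_ids:
        if sid == ped.affected_twin:
            continue
        if not _require_hom_ref(cls[sid], cfg, notes):
            return _REJECT
    return ScreenResult(True, frozenset(notes))


def autosomal_recessive_screen(
    v: AnnotatedVariant, ped: Pedigree, cfg: ModelConfig = ModelConfig()
) -> ScreenResult:
    """Affected twin 1/1, both parents 0/1 carriers, and no unaffected
    sibling or twin 1/1."""
    if not _autosome_gate(v, cfg):
        return _REJECT
    cls = _classes(v, ped)
    if cls[ped.affected_twin] != GenotypeClass.HOM_ALT:
        return _REJECT
    notes: set = set()
    for parent in ped.parents:
        if cls[parent] != GenotypeClass.HET:
            return _REJECT
    for sid in (*ped.siblings, ped.unaffected_twin):
        c = cls[sid]
        if c == GenotypeClass.HOM_ALT:
            return _REJECT
        if c == GenotypeClass.NO_CALL:
            if cfg.no_call_policy == "strict":
                return _REJECT
            notes.add(NOTE_NO_CALL)
    return ScreenResult(True, frozenset(notes))


def autosomal_dominant_screen(
    v: AnnotatedVariant, ped: Pedigree, cfg: ModelConfig = ModelConfig()
) -> ScreenResult:
    """Affected twin 0/1, everyone else 0/0; with incomplete penetrance on,
    exactly one parent may be 0/1 (noted as a penetrance exception)."""
    if not _autosome_gate(v, cfg):
        return _REJECT
    cls = _classes(v, ped)
    if cls[ped.affected_twin] != GenotypeClass.HET:
        return _REJECT
    notes: set = set()
    for sid in (*ped.siblings, ped.unaffected_twin):
        if not _require_hom_ref(cls[sid], cfg, notes):
            return _REJECT
    het_parents = [p for p in ped.parents if cls[p] == GenotypeClass.HET]
    ok_parents = all(
        _require_hom_ref(cls[p], cfg, notes)
        for p in ped.parents
        if p not in het_parents
    )
    if not ok_parents:
        return _REJECT
    if het_parents:
        if cfg.incomplete_penetrance and len(het_parents) == 1:
            notes.add(NOTE_PENETRANCE)
        else:
            return _REJECT
    return ScreenResult(True, frozenset(notes))


def homozygous_screen(
    v: AnnotatedVariant, ped: Pedigree, cfg: ModelConfig = ModelConfig()
) -> ScreenResult:
    """Affected twin hom_alt; others unconstrained.  A concordant_twin note is
    attached when the unaffected twin is hom_alt too (these are eliminated as
    causative downstream, but counted here)."""
    if not _autosome_gate(v, cfg):
        return _REJECT
    cls = _classes(v, ped)
    if cls[ped.affected_twin] != GenotypeClass.HOM_ALT:
        return _REJECT
    notes: set = set()
    if cls[ped.unaffected_twin] == GenotypeClass.HOM_ALT:
        notes.add(NOTE_CONCORDANT_TWIN)
    return ScreenResult(True, frozenset(notes))


#: Screen registry in reporting order.
MODEL_SCREENS = {
    "de_novo": de_novo_screen,
    "autosomal_recessive": autosomal_recessive_screen,
    "autosomal_dominant": autosomal_dominant_screen,
    "homozygous_screen": homozygous_screen,
}


def screen_cohort(
    variants: Iterable[AnnotatedVariant],
    ped: Pedigree,
    cfg: ModelConfig = ModelConfig(),
    models: Sequence[str] = tuple(MODEL_SCREENS),
) -> Dict[str, List[ModelCandidate]]:
    """Apply the requested model screens to every variant.

    Deterministic and order-independent: each variant is judged in isolation.
    """
    out: Dict[str, List[ModelCandidate]] = {m: [] for m in models}
    for v in variants:
        for m in models:
            res = MODEL_SCREENS[m](v, ped, cfg)
            if res.admitted:
                out[m].append(
                    ModelCandidate(variant=v, model=m, support_notes=res.notes)
                )
    return out


def twin_concordance(
    variants: Iterable[AnnotatedVariant], ped: Pedigree
) -> ConcordanceSummary:
    """Tally variant sharing between the twins.

    A variant is "present" in a twin iff that twin carries >= 1 alt allele;
    no-calls count as absent.  Sites present in neither twin do not enter the
    tallies.
    """
    shared = only_a = only_u = 0
    for v in variants:
        in_a = v.carries_alt(ped.affected_twin)
        in_u = v.carries_alt(ped.unaffected_twin)
        if in_a and in_u:
            shared += 1
        elif in_a:
            only_a += 1
        elif in_u:
            only_u += 1
    return ConcordanceSummary(
        shared_count=shared, unique_to_affected=only_a, unique_to_unaffected=only_u
    )
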