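"""Three-stage variant filter: quality/frequency/consequence gate, then a
liberal and a strict pathogenicity tier.

Stage order in the funnel: FILTER==PASS -> population rarity (max MAF <= 1%)
-> protein-altering consequence -> liberal tier (damaging by at least one of
SIFT / PolyPhen-2 HDIV / MutationTaster) -> strict tier (liberal plus
CADD > 20 and REVEL >= 0.5).  The strict tier is cumulative on the liberal
one, so strict survivors are always a subset of liberal survivors.

Note the asymmetric bounds: the CADD cut is strict (a variant at exactly 20
fails) while the REVEL cut is inclusive (exactly 0.5 passes).  Absent scores
never pass a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

from twinvar.core import AnnotatedVariant, AnnotationBundle, PathogenicityScores

DEFAULT_PROTEIN_ALTERING = frozenset(
    {
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "frameshift_insertion",
        "frameshift_deletion",
    }
)

DEFAULT_DAMAGING = {
    "sift": frozenset({"D"}),
    "polyphen2_hdiv": frozenset({"D", "P"}),
    "mutation_taster": frozenset({"D", "A"}),
}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and category sets for the filtering funnel.

    Defaults: MAF cutoff 1% (max over present population sources), PASS-only,
    exonic/splicing protein-altering consequences, CADD > 20 (strict
    inequality), REVEL >= 0.5 (inclusive).  PolyPhen-2 counts both D
    (probably) and P (possibly damaging) as damaging; MutationTaster counts
    D (disease-causing) and A (disease-causing automatic); SIFT counts D.
    """

    maf_threshold: float = 0.01
    require_pass: bool = True
    protein_altering_classes: FrozenSet[str] = DEFAULT_PROTEIN_ALTERING
    allowed_regions: FrozenSet[str] = frozenset({"exonic", "splicing"})
    cadd_min: float = 20.0
    revel_min: float = 0.5
    damaging_categories: Mapping[str, FrozenSet[str]] = field(
        default_factory=lambda: dict(DEFAULT_DAMAGING)
    )


def passes_quality(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff FILTER is exactly "PASS" (when require_pass); "." counts as
    not-PASS — an unfiltered record is not a high-confidence one."""
    if not cfg.require_pass:
        return True
    return v.filter_status == "PASS"


def is_rare(bundle: AnnotationBundle, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff the maximum population frequency over present sources is at
    most the MAF threshold; a variant absent from every database is retained
    (novel variants are the interesting ones)."""
    if not bundle.pop_freqs:
        return True
    return max(bundle.pop_freqs.values()) <= cfg.maf_threshold


def is_protein_altering(
    bundle: AnnotationBundle, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Consequence gate: exonic/splicing region and protein-altering class.

    A pure splicing variant with no exonic class (the annotator leaves it
    absent) still passes: splice disruption is protein-altering even without
    an exonic consequence label.
    """
    regions = bundle.regions
    if not regions & cfg.allowed_regions:
        return False
    if bundle.exonic_class in cfg.protein_altering_classes:
        return True
    return bundle.exonic_class is None and "splicing" in regions


def liberal_tier(
    scores: PathogenicityScores, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Damaging by at least one of SIFT, PolyPhen-2 HDIV, MutationTaster.

    Absent predictions contribute nothing (never pass).
    """
    tools = {
        "sift": scores.sift,
        "polyphen2_hdiv": scores.polyphen2_hdiv,
        "mutation_taster": scores.mutation_taster,
    }
    for name, call in tools.items():
        damaging = cfg.damaging_categories.get(name, frozenset())
        if call.category is not None and call.category in damaging:
            return True
    return False


def strict_tier(
    scores: PathogenicityScores, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Liberal tier plus quantitative thresholds CADD > 20 and REVEL >= 0.5.

    Absent CADD or REVEL fails: a variant cannot clear a bar it was never
    measured against.
    """
    if not liberal_tier(scores, cfg):
        return False
    if scores.cadd_phred is None or scores.revel is None:
        return False
    return scores.cadd_phred > cfg.cadd_min and scores.revel >= cfg.revel_min


#: Stage names in funnel order.
FUNNEL_STAGES = ("input", "quality", "rarity", "protein_altering", "liberal", "strict")


@dataclass(frozen=True)
class FunnelResult:
    """Ordered (stage, count) pairs for one filtering chain; counts are
    non-increasing along the chain by construction."""

    stages: Tuple[Tuple[str, int], ...]

    @property
    def counts(self) -> Dict[str, int]:
        return dict(self.stages)

    def __getitem__(self, stage: str) -> int:
        return self.counts[stage]


def apply_funnel(
    variants: Iterable[AnnotatedVariant], cfg: FilterConfig = FilterConfig()
) -> Tuple[FunnelResult, Dict[str, List[AnnotatedVariant]]]:
    """Run the staged filter chain, recording survivors and counts per stage.

    Returns the funnel counts and a map stage name -> surviving variants
    (including the untouched ``input`` stage).
    """
    survivors: Dict[str, List[AnnotatedVariant]] = {}
    current = list(variants)
    survivors["input"] = list(current)

    current = [v for v in current if passes_quality(v, cfg)]
    survivors["quality"] = list(current)

    current = [v for v in current if is_rare(v.bundle, cfg)]
    survivors["rarity"] = list(current)

    current = [v for v in current if is_protein_altering(v.bundle, cfg)]
    survivors["protein_altering"] = list(current)

    current = [v for v in current if liberal_tier(v.bundle.scores, cfg)]
    survivors["liberal"] = list(current)

    current = [v for v in current if strict_tier(v.bundle.scores, cfg)]
    survivors["strict"] = list(current)

    counts = tuple((stage, len(survivors[stage])) for stage in FUNNEL_STAGES)
    return FunnelResult(stages=counts), survivors
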