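"""Shared domain types: variant keys, genotype calls, annotation bundles.

Conventions
-----------
* Coordinates are VCF-native: 1-based, inclusive.  Chromosome names are kept
  verbatim (``chr10`` and ``10`` are distinct unless an alias map is applied
  upstream); hg19 inputs vary in this respect.
* Genotype alleles are encoded as ``0`` (REF), ``1`` (ALT) or ``None``
  (missing).  Multiallelic records are decomposed upstream, so an allele index
  above 1 never reaches these types.
* Half-calls (one known allele, one missing) classify as ``no_call``:
  genotypes the caller could not fully determine are treated as uncertain and
  routed to evidence review rather than trusted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

#: Closed vocabulary for the functional-region annotation slot.
FUNC_REGIONS = frozenset(
    {"exonic", "splicing", "exonic;splicing", "intronic", "UTR", "intergenic", "other"}
)

#: Closed vocabulary for the exonic consequence slot (``None`` = absent).
EXONIC_CLASSES = frozenset(
    {
        "nonsynonymous_SNV",
        "synonymous_SNV",
        "stopgain",
        "stoploss",
        "frameshift_insertion",
        "frameshift_deletion",
        "nonframeshift",
        "unknown",
    }
)

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def is_autosome(chrom: str) -> bool:
    """True for chr1..chr22 / 1..22 (case-insensitive ``chr`` prefix)."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name in _AUTOSOMES


class GenotypeClass(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


@dataclass(frozen=True, order=True)
class VariantKey:
    """One biallelic site: chromosome, 1-based position, ref and single alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # chr10:70587543:C>T style
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid genotype for one sample; alleles 0/1/None, phasing recorded but
    never consulted by classification."""

    sample_id: str
    alleles: Tuple[Optional[int], Optional[int]]
    phased: bool = False

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a is not None and a not in (0, 1):
                raise ValueError(
                    f"allele must be 0, 1 or None (missing); got {a!r} "
                    f"for sample {self.sample_id}"
                )


def classify_genotype(call: GenotypeCall) -> GenotypeClass:
    """Classify a genotype call as hom_ref / het / hom_alt / no_call.

    Total over all allele-pair combinations; any missing allele (including
    half-calls such as ``./1``) yields ``no_call``.  Phasing is ignored.
    """
    a, b = call.alleles
    if a is None or b is None:
        return GenotypeClass.NO_CALL
    if a == b:
        return GenotypeClass.HOM_ALT if a == 1 else GenotypeClass.HOM_REF
    return GenotypeClass.HET


@dataclass(frozen=True)
class ToolCall:
    """One in-silico predictor's output: categorical call plus raw score.

    Categories follow the tool's own alphabet (SIFT: D/T; PolyPhen-2 HDIV:
    D/P/B; MutationTaster: D/A/P/N).  ``category is None`` means the tool made
    no prediction; an absent call never counts as damaging.
    """

    category: Optional[str] = None
    score: Optional[float] = None


@dataclass(frozen=True)
class PathogenicityScores:
    """Per-variant pathogenicity annotations consumed (never computed) here.

    cadd_phred is the scaled CADD score (>20 ~ top 1% most deleterious);
    revel the ensemble missense score in [0, 1].  Absent scores never pass
    any threshold.
    """

    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    sift: ToolCall = ToolCall()
    polyphen2_hdiv: ToolCall = ToolCall()
    mutation_taster: ToolCall = ToolCall()

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD phred must be >= 0, got {self.cadd_phred}")
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"REVEL must be in [0,1], got {self.revel}")


@dataclass(frozen=True)
class AnnotationBundle:
    """Annotation attached to one decomposed variant.

    pop_freqs maps a frequency source (e.g. ``gnomad_exome``, ``gnomad_genome``,
    ``exac``) to the population allele frequency; sources the annotator did not
    report are simply absent from the map.
    """

    gene: Optional[str] = None
    func_region: Optional[str] = None
    exonic_class: Optional[str] = None
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    clinvar: Optional[str] = None
    scores: PathogenicityScores = PathogenicityScores()

    def __post_init__(self) -> None:
        if self.func_region is not None and self.func_region not in FUNC_REGIONS:
            raise ValueError(f"unknown func_region {self.func_region!r}")
        if self.exonic_class is not None and self.exonic_class not in EXONIC_CLASSES:
            raise ValueError(f"unknown exonic_class {self.exonic_class!r}")
        for src, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"pop_freq {src}={f} outside [0,1]")

    @property
    def regions(self) -> frozenset:
        """Region memberships; 'exonic;splicing' counts as both."""
        if self.func_region is None:
            return frozenset()
        return frozenset(self.func_region.split(";"))


@dataclass(frozen=True)
class AnnotatedVariant:
    """A biallelic site with its annotation bundle and per-sample genotypes.

    ``filter_status`` is the VCF FILTER column preserved verbatim.
    ``genotypes`` maps sample id -> GenotypeCall; family screens require it to
    cover every pedigree member and raise otherwise.
    """

    key: VariantKey
    filter_status: str = "PASS"
    bundle: AnnotationBundle = AnnotationBundle()
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)

    def genotype_class(self, sample_id: str) -> GenotypeClass:
        try:
            call = self.genotypes[sample_id]
        except KeyError:
            raise KeyError(
                f"no genotype for sample {sample_id!r} at {self.key}"
            ) from None
        return classify_genotype(call)

    def carries_alt(self, sample_id: str) -> bool:
        """True iff the sample carries at least one alt allele (het or hom_alt)."""
        return self.genotype_class(sample_id) in (
            GenotypeClass.HET,
            GenotypeClass.HOM_ALT,
        )
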