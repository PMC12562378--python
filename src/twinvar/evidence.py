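"""Read-evidence review: formalizing manual BAM/IGV inspection as flags.

Candidate variants from family screens are only as good as the reads beneath
them; this module turns per-sample pileup summaries (depth, alt reads, strand
split) into computable validation flags:

* ``low_depth`` — total depth below a floor (default 20x);
* ``low_alt_support`` — a called carrier with too few alt reads (< 3) or too
  low an alternate allele fraction (< 0.20);
* ``strand_bias`` — alt support concentrated on one strand: either all alt
  reads (>= 3 of them) on a single strand, or a two-sided Fisher exact test
  on the (ref, alt) x (fwd, rev) table significant at p < 0.05;
* ``aaf_genotype_conflict`` — the allele fraction is inconsistent with the
  called genotype (het outside [0.25, 0.75]; hom_alt below 0.90; hom_ref
  above 0.05).

Verdicts: ``likely_artifact`` when a called carrier shows low alt support or
strand bias; ``uncertain`` when only depth or an allele-fraction conflict (or
a no-call genotype) undermines the call; ``supported`` otherwise.  The cohort
verdict is the worst per-sample verdict among carriers.

The numeric thresholds are conventions, not published rules; they are chosen
to reproduce qualitative artifact/uncertain/supported judgements (e.g. a het
call at 9% allele fraction, or a 1/19-read homozygote, both flag as likely
artifacts) and every one is configurable.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

from scipy.stats import fisher_exact

from twinvar.core import AnnotatedVariant, GenotypeClass, VariantKey
from twinvar.pedigree import Pedigree


class Verdict(str, enum.Enum):
    SUPPORTED = "supported"
    UNCERTAIN = "uncertain"
    LIKELY_ARTIFACT = "likely_artifact"


_VERDICT_RANK = {
    Verdict.SUPPORTED: 0,
    Verdict.UNCERTAIN: 1,
    Verdict.LIKELY_ARTIFACT: 2,
}


def worst_verdict(verdicts: Sequence[Verdict]) -> Verdict:
    if not verdicts:
        return Verdict.UNCERTAIN
    return max(verdicts, key=_VERDICT_RANK.__getitem__)


@dataclass(frozen=True)
class ReviewEvidence:
    """Per-sample read support at one site (1-based position upstream)."""

    sample_id: str
    depth: int
    alt_reads: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int

    def __post_init__(self) -> None:
        if min(self.depth, self.alt_reads, self.alt_fwd, self.alt_rev,
               self.ref_fwd, self.ref_rev) < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_fwd + self.alt_rev != self.alt_reads:
            raise ValueError(
                f"strand split {self.alt_fwd}+{self.alt_rev} != alt_reads "
                f"{self.alt_reads} for {self.sample_id}"
            )
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth} "
                f"for {self.sample_id}"
            )


@dataclass(frozen=True)
class ReviewThresholds:
    min_depth: int = 20
    min_alt_reads: int = 3
    min_carrier_aaf: float = 0.20
    het_aaf_window: Tuple[float, float] = (0.25, 0.75)
    hom_alt_min_aaf: float = 0.90
    hom_ref_max_aaf: float = 0.05
    strand_p: float = 0.05
    strand_min_alt: int = 3  # all-one-strand rule needs at least this many alt reads


@dataclass(frozen=True)
class ReviewFlags:
    sample_id: str
    aaf: Optional[float]
    low_depth: bool
    low_alt_support: bool
    strand_bias: bool
    strand_p: float
    aaf_genotype_conflict: bool
    verdict: Verdict


def allele_fraction(ev: ReviewEvidence) -> Optional[float]:
    """alt_reads / depth; absent (None) at zero depth."""
    if ev.depth == 0:
        return None
    return ev.alt_reads / ev.depth


def strand_bias_flag(
    ev: ReviewEvidence, thresholds: ReviewThresholds = ReviewThresholds()
) -> Tuple[bool, float]:
    """Strand-bias flag plus the two-sided Fisher exact p-value.

    Flag is raised when all alt reads (at least ``strand_min_alt`` of them)
    sit on one strand, or when the Fisher test on
    [[ref_fwd, ref_rev], [alt_fwd, alt_rev]] rejects at ``strand_p``.
    """
    table = [[ev.ref_fwd, ev.ref_rev], [ev.alt_fwd, ev.alt_rev]]
    p = float(fisher_exact(table, alternative="two-sided")[1])
    one_sided = ev.alt_reads >= thresholds.strand_min_alt and (
        ev.alt_fwd == 0 or ev.alt_rev == 0
    )
    return one_sided or p < thresholds.strand_p, p


def review_sample(
    genotype_class: GenotypeClass,
    ev: ReviewEvidence,
    thresholds: ReviewThresholds = ReviewThresholds(),
) -> ReviewFlags:
    """Flags and verdict for one sample's evidence at one site."""
    aaf = allele_fraction(ev)
    low_depth = ev.depth < thresholds.min_depth
    is_carrier = genotype_class in (GenotypeClass.HET, GenotypeClass.HOM_ALT)
    low_alt = False
    if is_carrier:
        low_alt = ev.alt_reads < thresholds.min_alt_reads or (
            aaf is not None and aaf < thresholds.min_carrier_aaf
        )
    bias, p = strand_bias_flag(ev, thresholds)
    # strand bias is only meaningful where alt support exists
    bias = bias and ev.alt_reads > 0

    conflict = False
    if aaf is not None:
        lo, hi = thresholds.het_aaf_window
        if genotype_class == GenotypeClass.HET:
            conflict = not (lo <= aaf <= hi)
        elif genotype_class == GenotypeClass.HOM_ALT:
            conflict = aaf < thresholds.hom_alt_min_aaf
        elif genotype_class == GenotypeClass.HOM_REF:
            conflict = aaf > thresholds.hom_ref_max_aaf

    if genotype_class == GenotypeClass.NO_CALL:
        verdict = Verdict.UNCERTAIN
    elif is_carrier and (low_alt or bias):
        verdict = Verdict.LIKELY_ARTIFACT
    elif low_depth or conflict or (aaf is None):
        verdict = Verdict.UNCERTAIN
    else:
        verdict = Verdict.SUPPORTED
    return ReviewFlags(
        sample_id=ev.sample_id,
        aaf=aaf,
        low_depth=low_depth,
        low_alt_support=low_alt,
        strand_bias=bias,
        strand_p=p,
        aaf_genotype_conflict=conflict,
        verdict=verdict,
    )


def review_variant(
    v: AnnotatedVariant,
    evidence: Mapping[str, ReviewEvidence],
    ped: Pedigree,
    thresholds: ReviewThresholds = ReviewThresholds(),
) -> Tuple[Dict[str, ReviewFlags], Verdict]:
    """Per-sample review flags plus a cohort verdict for one variant.

    Evidence must cover at least the twin pair; every evidence sample must
    have a genotype in the variant.  The cohort verdict is the worst verdict
    among alt-carrying samples (carriers are where an artifact would matter);
    if no carrier has evidence, it is ``uncertain``.
    """
    for twin in ped.twin_pair:
        if twin not in evidence:
            raise ValueError(f"no review evidence for twin {twin!r} at {v.key}")
    flags: Dict[str, ReviewFlags] = {}
    carrier_verdicts = []
    for sid, ev in evidence.items():
        if sid not in v.genotypes:
            raise ValueError(
                f"evidence sample {sid!r} has no genotype at {v.key}"
            )
        cls = v.genotype_class(sid)
        fl = review_sample(cls, ev, thresholds)
        flags[sid] = fl
        if cls in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
            carrier_verdicts.append(fl.verdict)
    return flags, worst_verdict(carrier_verdicts)


# ---------------------------------------------------------------------------
# Pileup-summary TSV
# ---------------------------------------------------------------------------

_PILEUP_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_fwd",
    "alt_rev",
    "ref_fwd",
    "ref_rev",
]


def read_pileup_summary(
    source: Union[str, Path]
) -> Dict[VariantKey, Dict[str, ReviewEvidence]]:
    """Read a pileup-summary TSV (1-based positions) into evidence maps.

    Columns: sample, chrom, pos, ref, alt, depth, alt_fwd, alt_rev, ref_fwd,
    ref_rev.  Returns variant key -> {sample -> evidence}.
    """
    out: Dict[VariantKey, Dict[str, ReviewEvidence]] = {}
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PILEUP_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"pileup summary missing column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            key = VariantKey(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"]
            )
            ev = ReviewEvidence(
                sample_id=row["sample"],
                depth=int(row["depth"]),
                alt_reads=int(row["alt_fwd"]) + int(row["alt_rev"]),
                alt_fwd=int(row["alt_fwd"]),
                alt_rev=int(row["alt_rev"]),
                ref_fwd=int(row["ref_fwd"]),
                ref_rev=int(row["ref_rev"]),
            )
            out.setdefault(key, {})[ev.sample_id] = ev
    return out


def write_pileup_summary(
    rows: Mapping[VariantKey, Mapping[str, ReviewEvidence]],
    destination: Union[str, Path],
) -> None:
    lines = ["\t".join(_PILEUP_COLUMNS)]
    for key in sorted(rows, key=lambda k: (k.chrom, k.pos, k.alt)):
        for sid in sorted(rows[key]):
            ev = rows[key][sid]
            lines.append(
                "\t".join(
                    str(x)
                    for x in [
                        sid,
                        key.chrom,
                        key.pos,
                        key.ref,
                        key.alt,
                        ev.depth,
                        ev.alt_fwd,
                        ev.alt_rev,
                        ev.ref_fwd,
                        ev.ref_rev,
                    ]
                )
            )
    Path(destination).write_text("\n".join(lines) + "\n")
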