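"""Multi-sample VCF input with ANNOVAR-dialect annotation mapping, plus the
tab-separated candidate tables.

Reading goes through pysam; records are decomposed to biallelic on the fly.
The decomposition policy: in a record decomposed against alt *k*, sample
alleles equal to *k* become 1, reference stays 0, and any *other* alt allele
becomes missing — a 1/2 genotype therefore reads as a half-call for each
decomposed alt, never as hom_ref, so model screens cannot be fooled by a
phantom reference genotype.

Annotation INFO keys vary by ANNOVAR release; an :class:`AnnotationDialect`
maps semantic slots (gene, region, scores, population frequencies, ...) to
INFO keys and is fully overridable from a flat ``slot=KEY`` config file.
Unmappable or absent fields become absent values, never defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pysam

from twinvar.core import (
    EXONIC_CLASSES,
    AnnotatedVariant,
    AnnotationBundle,
    GenotypeCall,
    PathogenicityScores,
    ToolCall,
    VariantKey,
)


class VcfFormatError(ValueError):
    """Malformed or inconsistent VCF content (message carries line context)."""


# ---------------------------------------------------------------------------
# Annotation dialect
# ---------------------------------------------------------------------------

#: Default slot -> INFO key map, following ANNOVAR table-output naming.
DEFAULT_FIELD_MAP: Dict[str, str] = {
    "gene": "Gene.refGene",
    "func_region": "Func.refGene",
    "exonic_class": "ExonicFunc.refGene",
    "aa_change": "AAChange.refGene",
    "cadd_phred": "CADD_phred",
    "revel": "REVEL",
    "sift_pred": "SIFT_pred",
    "sift_score": "SIFT_score",
    "polyphen2_hdiv_pred": "Polyphen2_HDIV_pred",
    "polyphen2_hdiv_score": "Polyphen2_HDIV_score",
    "mutation_taster_pred": "MutationTaster_pred",
    "mutation_taster_score": "MutationTaster_score",
    "freq_gnomad_exome": "gnomAD_exome_ALL",
    "freq_gnomad_genome": "gnomAD_genome_ALL",
    "freq_exac": "ExAC_ALL",
    "clinvar": "CLNSIG",
}

#: Slots holding population frequencies, mapped to pop_freqs source names.
_FREQ_SLOTS = {
    "freq_gnomad_exome": "gnomad_exome",
    "freq_gnomad_genome": "gnomad_genome",
    "freq_exac": "exac",
}

# Normalization of annotator region/class vocabulary onto the closed sets.
_REGION_MAP = {
    "exonic": "exonic",
    "splicing": "splicing",
    "exonic;splicing": "exonic;splicing",
    "intronic": "intronic",
    "UTR3": "UTR",
    "UTR5": "UTR",
    "UTR5;UTR3": "UTR",
    "intergenic": "intergenic",
}


@dataclass(frozen=True)
class AnnotationDialect:
    """Mapping from semantic annotation slots to INFO keys.

    ``missing_token`` is the annotator's in-band null (ANNOVAR writes ``.``).
    """

    field_name_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_MAP)
    )
    missing_token: str = "."

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AnnotationDialect":
        """Load overrides from a flat ``slot=INFO_KEY`` file; unlisted slots
        keep their defaults.  ``missing_token=`` overrides the null token."""
        mapping = dict(DEFAULT_FIELD_MAP)
        missing = "."
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise VcfFormatError(f"dialect line {lineno}: expected slot=KEY")
            slot, key = (s.strip() for s in line.split("=", 1))
            if slot == "missing_token":
                missing = key
            else:
                mapping[slot] = key
        return cls(field_name_map=mapping, missing_token=missing)


def _decode(value: str) -> str:
    """Undo VCF INFO percent/backslash escaping used by annotators."""
    return (
        value.replace("\\x3b", ";")
        .replace("%3B", ";")
        .replace("\\x3d", "=")
        .replace("%3D", "=")
    )


def _normalize_region(value: str) -> Optional[str]:
    return _REGION_MAP.get(value, "other")


def _normalize_exonic_class(value: str) -> str:
    token = value.replace(" ", "_")
    if token.startswith("nonframeshift"):
        return "nonframeshift"
    return token if token in EXONIC_CLASSES else "unknown"


_CHANGE_RE = re.compile(r"(c\.[^:;,]+)|(p\.[^:;,]+)")


def _extract_changes(aa_change: str) -> Tuple[Optional[str], Optional[str]]:
    """Pull the first c. and p. tokens out of an AAChange-style string
    (``GENE:NM_...:exon1:c.C163T:p.R55C``)."""
    cdna = protein = None
    for m in _CHANGE_RE.finditer(aa_change):
        if m.group(1) and cdna is None:
            cdna = m.group(1)
        if m.group(2) and protein is None:
            protein = m.group(2)
    return cdna, protein


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _info_str(
    record: "pysam.VariantRecord", dialect: AnnotationDialect, slot: str
) -> Optional[str]:
    key = dialect.field_name_map.get(slot)
    if key is None:
        return None
    try:
        value = record.info.get(key)
    except (KeyError, ValueError):  # key absent from header: treat as absent
        return None
    if value is None:
        return None
    if isinstance(value, tuple):
        value = ",".join(str(v) for v in value)
    value = str(value)
    if value == dialect.missing_token or value == "":
        return None
    return _decode(value)


def _info_float(
    record: "pysam.VariantRecord", dialect: AnnotationDialect, slot: str
) -> Optional[float]:
    raw = _info_str(record, dialect, slot)
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _tool_call(
    record: "pysam.VariantRecord",
    dialect: AnnotationDialect,
    pred_slot: str,
    score_slot: str,
) -> ToolCall:
    return ToolCall(
        category=_info_str(record, dialect, pred_slot),
        score=_info_float(record, dialect, score_slot),
    )


def _bundle_from_record(
    record: "pysam.VariantRecord", dialect: AnnotationDialect
) -> AnnotationBundle:
    region_raw = _info_str(record, dialect, "func_region")
    exonic_raw = _info_str(record, dialect, "exonic_class")
    aa_change = _info_str(record, dialect, "aa_change")
    cdna, protein = _extract_changes(aa_change) if aa_change else (None, None)
    pop_freqs: Dict[str, float] = {}
    for slot, source in _FREQ_SLOTS.items():
        f = _info_float(record, dialect, slot)
        if f is not None:
            pop_freqs[source] = f
    return AnnotationBundle(
        gene=_info_str(record, dialect, "gene"),
        func_region=_normalize_region(region_raw) if region_raw else None,
        exonic_class=_normalize_exonic_class(exonic_raw) if exonic_raw else None,
        cdna_change=cdna,
        protein_change=protein,
        pop_freqs=pop_freqs,
        clinvar=_info_str(record, dialect, "clinvar"),
        scores=PathogenicityScores(
            cadd_phred=_info_float(record, dialect, "cadd_phred"),
            revel=_info_float(record, dialect, "revel"),
            sift=_tool_call(record, dialect, "sift_pred", "sift_score"),
            polyphen2_hdiv=_tool_call(
                record, dialect, "polyphen2_hdiv_pred", "polyphen2_hdiv_score"
            ),
            mutation_taster=_tool_call(
                record, dialect, "mutation_taster_pred", "mutation_taster_score"
            ),
        ),
    )


def _remap_allele(allele: Optional[int], alt_index: int) -> Optional[int]:
    """Decomposition rule: current alt -> 1, ref -> 0, other alt -> missing."""
    if allele is None:
        return None
    if allele == 0:
        return 0
    if allele == alt_index:
        return 1
    return None


def read_cohort(
    vcf_source: Union[str, Path],
    dialect: AnnotationDialect = AnnotationDialect(),
    expected_samples: Optional[Sequence[str]] = None,
) -> List[AnnotatedVariant]:
    """Read a (possibly bgzipped) multi-sample VCF into annotated variants.

    Yields one variant per (site, alt allele) after multiallelic
    decomposition.  Every sample listed in ``expected_samples`` must appear in
    the header; a missing one is a hard error naming the sample.
    """
    vcf = pysam.VariantFile(str(vcf_source))
    header_samples = list(vcf.header.samples)
    if expected_samples is not None:
        missing = [s for s in expected_samples if s not in header_samples]
        if missing:
            raise VcfFormatError(
                f"expected sample(s) {', '.join(missing)} not in VCF header "
                f"of {vcf_source}"
            )
    out: List[AnnotatedVariant] = []
    for record in vcf:
        alts = record.alts or ()
        if not alts:
            continue
        # pysam: FILTER '.' -> empty keys; PASS -> ['PASS']
        filter_keys = list(record.filter.keys())
        filter_status = ";".join(filter_keys) if filter_keys else "."
        bundle = _bundle_from_record(record, dialect)
        for alt_index, alt in enumerate(alts, start=1):
            if alt is None or alt.startswith("<"):
                continue  # symbolic alts out of scope
            try:
                key = VariantKey(
                    chrom=record.chrom, pos=record.pos, ref=record.ref, alt=alt
                )
            except ValueError as exc:
                raise VcfFormatError(
                    f"{record.chrom}:{record.pos}: {exc}"
                ) from exc
            genotypes: Dict[str, GenotypeCall] = {}
            for sid in header_samples:
                sample = record.samples[sid]
                gt = sample.get("GT", (None, None))
                if gt is None:
                    gt = (None, None)
                if len(gt) == 1:  # haploid call: treat as half-call
                    gt = (gt[0], None)
                if len(gt) != 2:
                    raise VcfFormatError(
                        f"{record.chrom}:{record.pos} sample {sid}: "
                        f"non-diploid genotype {gt!r}"
                    )
                genotypes[sid] = GenotypeCall(
                    sample_id=sid,
                    alleles=(
                        _remap_allele(gt[0], alt_index),
                        _remap_allele(gt[1], alt_index),
                    ),
                    phased=bool(sample.phased),
                )
            out.append(
                AnnotatedVariant(
                    key=key,
                    filter_status=filter_status,
                    bundle=bundle,
                    genotypes=genotypes,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------

_CHROM_SPECIAL = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> Tuple[int, str]:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    return (_CHROM_SPECIAL.get(name.upper(), 99), name)


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return "."
    return f"{x:g}"


def _fmt_tool(call: ToolCall) -> str:
    if call.category is None:
        return "."
    if call.score is None:
        return call.category
    return f"{call.category} ({call.score:g})"


_TOOL_RE = re.compile(r"^([A-Za-z])\s*(?:\(([^)]+)\))?$")


def _parse_tool(text: str) -> ToolCall:
    text = text.strip()
    if text in (".", "-", ""):
        return ToolCall()
    m = _TOOL_RE.match(text)
    if not m:
        raise VcfFormatError(f"unparseable tool prediction {text!r}")
    score = float(m.group(2)) if m.group(2) is not None else None
    return ToolCall(category=m.group(1), score=score)


def _parse_num(text: str) -> Optional[float]:
    text = text.strip()
    if text in (".", "-", ""):
        return None
    return float(text)


_GT_STR = {
    (0, 0): "0/0",
    (0, 1): "0/1",
    (1, 0): "0/1",
    (1, 1): "1/1",
}

_FIXED_COLUMNS = [
    "Gene",
    "Chr",
    "Pos",
    "Ref",
    "Alt",
    "cDNA",
    "Protein",
    "ExonicFunc",
    "CADD",
    "REVEL",
    "SIFT",
    "PolyPhen2",
    "MutationTaster",
]


def write_candidates(
    candidates: Sequence,
    destination: Union[str, Path],
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Write model candidates (or bare variants) as a TSV candidate table.

    Row order is deterministic: natural chromosome order, then position, then
    alt allele.  ``candidates`` may mix :class:`AnnotatedVariant` and objects
    with ``.variant`` / ``.model`` attributes (model candidates); bare
    variants get an empty model label.
    """
    rows: List[Tuple[AnnotatedVariant, str]] = []
    for c in candidates:
        if hasattr(c, "variant"):
            rows.append((c.variant, c.model))
        else:
            rows.append((c, ""))
    rows.sort(key=lambda r: (chrom_sort_key(r[0].key.chrom), r[0].key.pos, r[0].key.alt))

    if samples is None:
        seen: List[str] = []
        for v, _ in rows:
            for sid in v.genotypes:
                if sid not in seen:
                    seen.append(sid)
        samples = seen

    header = _FIXED_COLUMNS + list(samples) + ["Model"]
    lines = ["\t".join(header)]
    for v, model in rows:
        b = v.bundle
        s = b.scores
        gt_cells = []
        for sid in samples:
            call = v.genotypes.get(sid)
            if call is None:
                gt_cells.append("./.")
                continue
            a, bb = call.alleles
            if a is None or bb is None:
                gt_cells.append("./.")
            else:
                gt_cells.append(_GT_STR[(a, bb)])
        lines.append(
            "\t".join(
                [
                    b.gene or ".",
                    v.key.chrom,
                    str(v.key.pos),
                    v.key.ref,
                    v.key.alt,
                    b.cdna_change or ".",
                    b.protein_change or ".",
                    b.exonic_class or ".",
                    _fmt_num(s.cadd_phred),
                    _fmt_num(s.revel),
                    _fmt_tool(s.sift),
                    _fmt_tool(s.polyphen2_hdiv),
                    _fmt_tool(s.mutation_taster),
                ]
                + gt_cells
                + [model]
            )
        )
    Path(destination).write_text("\n".join(lines) + "\n")


def read_candidates(source: Union[str, Path]) -> List:
    """Read a candidate table written by :func:`write_candidates`.

    Returns model candidates whose variants carry ``filter_status="PASS"``
    (candidate tables are emitted downstream of the quality gate).
    """
    from twinvar.inheritance import ModelCandidate  # local import: avoid cycle

    lines = Path(source).read_text().splitlines()
    if not lines:
        raise VcfFormatError(f"empty candidate table: {source}")
    header = lines[0].split("\t")
    if header[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
        raise VcfFormatError(f"unexpected candidate table header in {source}")
    samples = header[len(_FIXED_COLUMNS) : -1]
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        fixed = dict(zip(_FIXED_COLUMNS, cells))
        genotypes: Dict[str, GenotypeCall] = {}
        for sid, gt in zip(samples, cells[len(_FIXED_COLUMNS) : -1]):
            alleles: Tuple[Optional[int], Optional[int]]
            if gt == "./.":
                alleles = (None, None)
            else:
                a, b = gt.replace("|", "/").split("/")
                alleles = (
                    None if a == "." else int(a),
                    None if b == "." else int(b),
                )
            genotypes[sid] = GenotypeCall(sample_id=sid, alleles=alleles)
        variant = AnnotatedVariant(
            key=VariantKey(
                chrom=fixed["Chr"],
                pos=int(fixed["Pos"]),
                ref=fixed["Ref"],
                alt=fixed["Alt"],
            ),
            filter_status="PASS",
            bundle=AnnotationBundle(
                gene=None if fixed["Gene"] == "." else fixed["Gene"],
                func_region="exonic",
                exonic_class=None
                if fixed["ExonicFunc"] == "."
                else fixed["ExonicFunc"],
                cdna_change=None if fixed["cDNA"] == "." else fixed["cDNA"],
                protein_change=None if fixed["Protein"] == "." else fixed["Protein"],
                scores=PathogenicityScores(
                    cadd_phred=_parse_num(fixed["CADD"]),
                    revel=_parse_num(fixed["REVEL"]),
                    sift=_parse_tool(fixed["SIFT"]),
                    polyphen2_hdiv=_parse_tool(fixed["PolyPhen2"]),
                    mutation_taster=_parse_tool(fixed["MutationTaster"]),
                ),
            ),
            genotypes=genotypes,
        )
        out.append(
            ModelCandidate(variant=variant, model=cells[-1], support_notes=frozenset())
        )
    return out
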