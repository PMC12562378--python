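"""Bundled reference tables for the discordant-twin congenital scoliosis case.

Three published candidate-variant tables (de novo, autosomal recessive,
autosomal dominant) with their in-silico pathogenicity annotations, the
per-sample exome QC metrics table, and a synthetic example gene panel.

Genomic coordinates are published only for STOX1 (chr10:70587543), HOXD8
(chr2:176995144) and C1QTNF9 (chr13:24895332); the remaining rows carry
deterministic placeholder positions (1000001, 1000002, ...) and coding-strand
ref/alt alleles derived from the cDNA change, sufficient for score-level
analyses but not for genomic lookup.  The HOXD8 cDNA string is preserved
verbatim from the source table even though it is missing its reference base.

The example panel (``panel_synthetic.tsv``) reproduces the study panel's
category sizes (19 KFS / 24 CS / 83 other CSD) using a core of well-known
spinal-deformity genes padded with clearly labelled synthetic placeholder
symbols; it is a fixture for exercising the panel screen, not a curated
clinical resource.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List

import pandas as pd

from twinvar.core import (
    AnnotatedVariant,
    AnnotationBundle,
    PathogenicityScores,
    VariantKey,
)
from twinvar.panel import GenePanel, load_panel
from twinvar.vcf_io import _parse_num, _parse_tool


def _data_path(name: str) -> Path:
    return Path(resources.files("twinvar").joinpath("data", name))  # type: ignore[arg-type]


@dataclass(frozen=True)
class ReferenceCandidate:
    """One published candidate row: gene, site key and annotation bundle."""

    gene: str
    key: VariantKey
    exon: str
    bundle: AnnotationBundle

    @property
    def scores(self) -> PathogenicityScores:
        return self.bundle.scores

    def as_variant(self, filter_status: str = "PASS") -> AnnotatedVariant:
        """View as an AnnotatedVariant (no genotypes; candidate tables are
        reported downstream of the genotype screens)."""
        return AnnotatedVariant(
            key=self.key, filter_status=filter_status, bundle=self.bundle
        )


def _load_candidate_table(name: str) -> List[ReferenceCandidate]:
    out: List[ReferenceCandidate] = []
    lines = _data_path(name).read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        out.append(
            ReferenceCandidate(
                gene=row["Gene"],
                key=VariantKey(
                    chrom=row["Chr"], pos=int(row["Pos"]),
                    ref=row["Ref"], alt=row["Alt"],
                ),
                exon=row["Exon"],
                bundle=AnnotationBundle(
                    gene=row["Gene"],
                    func_region="exonic",
                    exonic_class=row["ExonicFunc"],
                    cdna_change=row["cDNA"],
                    protein_change=row["Protein"],
                    scores=PathogenicityScores(
                        cadd_phred=_parse_num(row["CADD"]),
                        revel=_parse_num(row["REVEL"]),
                        sift=_parse_tool(row["SIFT"]),
                        polyphen2_hdiv=_parse_tool(row["PolyPhen2"]),
                        mutation_taster=_parse_tool(row["MutationTaster"]),
                    ),
                ),
            )
        )
    return out


def load_denovo_candidates() -> List[ReferenceCandidate]:
    """The five published de novo candidate variants."""
    return _load_candidate_table("denovo_candidates.tsv")


def load_recessive_candidates() -> List[ReferenceCandidate]:
    """The four published autosomal recessive candidate variants."""
    return _load_candidate_table("recessive_candidates.tsv")


def load_dominant_candidates() -> List[ReferenceCandidate]:
    """The six published autosomal dominant candidate variants."""
    return _load_candidate_table("dominant_candidates.tsv")


def load_qc_metrics() -> pd.DataFrame:
    """Published per-sample exome coverage metrics for the eight-member family."""
    from twinvar.qc import read_qc_metrics

    return read_qc_metrics(_data_path("qc_metrics.tsv"))


def load_example_panel() -> GenePanel:
    """The synthetic 126-gene example panel (19 KFS / 24 CS / 83 other CSD)."""
    return load_panel(_data_path("panel_synthetic.tsv"))
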