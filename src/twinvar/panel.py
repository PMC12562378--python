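"""Curated gene-panel screen: collect variants in congenital-spinal-deformity
genes and test per-gene twin genotype concordance.

Panel categories: ``KFS`` (Klippel-Feil syndrome), ``CS`` (congenital
scoliosis) and ``OTHER_CSD`` (other congenital spinal deformities).  Gene
matching is by exact case-insensitive symbol; an annotation carrying a
semicolon-joined multi-gene symbol (as annotators emit at gene boundaries)
matches if any component matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from twinvar.core import AnnotatedVariant, GenotypeClass
from twinvar.pedigree import Pedigree

CATEGORIES = frozenset({"KFS", "CS", "OTHER_CSD"})


@dataclass(frozen=True)
class PanelEntry:
    gene: str  # stored uppercased
    category: str
    note: str = ""


@dataclass(frozen=True)
class GenePanel:
    entries: Tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols in panel")
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown panel category {e.category!r}")

    @property
    def genes(self) -> Tuple[str, ...]:
        return tuple(e.gene for e in self.entries)

    def category_counts(self) -> Dict[str, int]:
        out = {c: 0 for c in sorted(CATEGORIES)}
        for e in self.entries:
            out[e.category] += 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


def load_panel(panel_source: Union[str, Path]) -> GenePanel:
    """Load a two/three-column TSV (gene, category[, note]) panel.

    Symbols are uppercased; a symbol listed more than once is collapsed to
    its first entry with a warning (the unique-gene count drops accordingly).
    Unknown categories are a hard error.
    """
    entries: List[PanelEntry] = []
    seen: Dict[str, str] = {}
    for lineno, raw in enumerate(Path(panel_source).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 2:
            raise ValueError(f"panel line {lineno}: expected gene<TAB>category")
        gene = cells[0].strip().upper()
        category = cells[1].strip()
        if category not in CATEGORIES:
            raise ValueError(
                f"panel line {lineno}: unknown category {category!r} "
                f"(expected one of {sorted(CATEGORIES)})"
            )
        if gene in seen:
            warnings.warn(
                f"panel gene {gene} listed again in category {category} "
                f"(kept {seen[gene]}); collapsing duplicates",
                stacklevel=2,
            )
            continue
        seen[gene] = category
        entries.append(
            PanelEntry(gene=gene, category=category,
                       note=cells[2].strip() if len(cells) > 2 else "")
        )
    return GenePanel(entries=tuple(entries))


@dataclass(frozen=True)
class PanelGeneResult:
    gene: str
    category: str
    variants: Tuple[AnnotatedVariant, ...]
    twin_concordant: bool  # identical genotype classes at every variant


@dataclass(frozen=True)
class PanelReport:
    per_gene: Tuple[PanelGeneResult, ...]

    @property
    def genes_screened(self) -> int:
        return len(self.per_gene)

    @property
    def genes_with_variants(self) -> int:
        return sum(1 for g in self.per_gene if g.variants)

    @property
    def genes_with_discordance(self) -> int:
        return sum(1 for g in self.per_gene if g.variants and not g.twin_concordant)

    def totals(self) -> Dict[str, int]:
        return {
            "genes_screened": self.genes_screened,
            "genes_with_variants": self.genes_with_variants,
            "genes_with_discordance": self.genes_with_discordance,
        }


def _gene_matches(annotation_gene: Optional[str], panel_gene: str) -> bool:
    if annotation_gene is None:
        return False
    return panel_gene in (g.strip().upper() for g in annotation_gene.split(";"))


def panel_screen(
    variants: Iterable[AnnotatedVariant],
    panel: GenePanel,
    ped: Pedigree,
) -> PanelReport:
    """Collect panel-gene variants and test twin genotype concordance per gene.

    A gene is twin-concordant iff the two twins' genotype classes are
    identical at every variant annotated to it (vacuously true with no
    variants).  Totals obey genes_with_discordance <= genes_with_variants <=
    genes_screened.
    """
    variants = list(variants)
    results: List[PanelGeneResult] = []
    for entry in panel.entries:
        hits = tuple(
            v for v in variants if _gene_matches(v.bundle.gene, entry.gene)
        )
        concordant = all(
            v.genotype_class(ped.affected_twin) == v.genotype_class(ped.unaffected_twin)
            for v in hits
        )
        results.append(
            PanelGeneResult(
                gene=entry.gene,
                category=entry.category,
                variants=hits,
                twin_concordant=concordant,
            )
        )
    return PanelReport(per_gene=tuple(results))
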