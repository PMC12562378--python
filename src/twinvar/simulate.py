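"""Synthetic discordant-twin exome cohorts with known ground truth.

The generator emits everything the pipeline consumes — a jointly genotyped
multi-sample VCFv4.2 with ANNOVAR-style INFO annotations, a pileup-summary
TSV, a per-sample QC-metrics TSV, a PED file and a truth table — for a family
with two founder parents, siblings, and an MZ twin pair discordant for the
phenotype.

Statistical structure
---------------------
* **Background sites** are unlinked biallelic exome variants.  Population
  allele frequencies are drawn from a Beta(0.5, 5) truncated to
  [1e-4, 0.5] (a rare-skewed site-frequency spectrum); founder genotypes are
  binomial draws from the site frequency, offspring follow Mendelian
  transmission, and the twins are genotype-identical by construction.
* **Planted sites** have genotypes set deterministically to the admitting
  pattern of one inheritance model (de novo: alt in the affected twin only;
  recessive: 1/1 affected, 0/1 parents; dominant: 0/1 affected, 0/0 others;
  homozygous-concordant: 1/1 in both twins).  Their annotation scores are
  drawn to hit a per-variant pathogenicity tier target (``strict_pass``,
  ``liberal_only`` or ``fail``) and their population frequencies are below
  1e-3, so the filtering funnel treats them as intended.
* **Artifacts** reproduce the failure modes seen in real review: low total
  depth, all-one-strand alt support, no-calls in every non-affected member,
  and a het call whose pileup shows only ~9% alternate allele fraction.

Planted de novo and dominant sites are genuine transmission violations (both
parents 0/0); their keys are returned as the Mendelian-check exempt set.

Reproducibility: one global seed, split into per-component child streams;
the same seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from twinvar.core import GenotypeClass, VariantKey
from twinvar.evidence import ReviewEvidence, write_pileup_summary
from twinvar.pedigree import Member, Pedigree, write_pedigree
from twinvar.vcf_io import chrom_sort_key

MODELS = ("de_novo", "autosomal_recessive", "autosomal_dominant", "homozygous_concordant")
TIERS = ("strict_pass", "liberal_only", "fail")
ARTIFACTS = ("low_depth", "strand_biased_alt", "no_call_others", "low_aaf_carrier")


@dataclass(frozen=True)
class ArtifactSpec:
    """Inject one artifact into the index-th planted variant of a model."""

    model: str
    index: int
    kind: str

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.kind not in ARTIFACTS:
            raise ValueError(f"unknown artifact {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for one simulated cohort.

    Defaults model a desk-scale version of an eight-member WES family:
    1000 unlinked rare-skewed background sites and a handful of planted
    model-specific candidates, all strict-tier unless overridden via
    ``tier_targets`` (model -> per-variant tier list).
    """

    seed: int
    n_background_sites: int = 1000
    allele_freq_alpha: float = 0.5
    allele_freq_beta: float = 5.0
    allele_freq_min: float = 1e-4
    allele_freq_max: float = 0.5
    n_de_novo: int = 2
    n_autosomal_recessive: int = 2
    n_autosomal_dominant: int = 2
    n_homozygous_concordant: int = 2
    tier_targets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    artifact_injections: Tuple[ArtifactSpec, ...] = ()
    panel_spike_gene: Optional[str] = None
    mean_site_depth: float = 160.0

    def __post_init__(self) -> None:
        counts = self.planted_counts()
        if any(c < 0 for c in counts.values()) or self.n_background_sites < 0:
            raise ValueError("site counts must be non-negative")
        if sum(counts.values()) > self.n_background_sites:
            raise ValueError(
                "planted variant count exceeds the background-site context"
            )
        for model, tiers in self.tier_targets.items():
            if model not in MODELS:
                raise ValueError(f"tier_targets: unknown model {model!r}")
            if len(tiers) != counts[model]:
                raise ValueError(
                    f"tier_targets[{model!r}] must list {counts[model]} tiers"
                )
            for t in tiers:
                if t not in TIERS:
                    raise ValueError(f"unknown tier target {t!r}")
        for a in self.artifact_injections:
            if a.index >= counts[a.model]:
                raise ValueError(
                    f"artifact index {a.index} out of range for {a.model}"
                )

    def planted_counts(self) -> Dict[str, int]:
        return {
            "de_novo": self.n_de_novo,
            "autosomal_recessive": self.n_autosomal_recessive,
            "autosomal_dominant": self.n_autosomal_dominant,
            "homozygous_concordant": self.n_homozygous_concordant,
        }

    def tier_for(self, model: str, index: int) -> str:
        return self.tier_targets.get(model, ["strict_pass"] * self.planted_counts()[model])[index]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted site."""

    key: VariantKey
    label: str  # model name, "panel_spike" or "background"
    tier: Optional[str]  # planted sites only
    artifact: Optional[str]
    genotypes: Mapping[str, str]  # sample -> "0/0" / "0/1" / "1/1" / "./."
    gene: str


@dataclass(frozen=True)
class SimBundle:
    """File paths plus in-memory truth for one simulated cohort."""

    vcf: Path
    pileup: Path
    qc: Path
    truth: Path
    ped: Path
    truth_records: Tuple[TruthRecord, ...]
    mendelian_exempt: frozenset  # keys planted as transmission violations


def study_pedigree() -> Pedigree:
    """The eight-member study family: father WES-001, mother WES-002, four
    unaffected siblings WES-003..006, unaffected twin WES-007, affected twin
    WES-008."""
    members = [Member("WES-001", None, None, "male", False),
               Member("WES-002", None, None, "female", False)]
    for i in range(3, 9):
        sid = f"WES-{i:03d}"
        members.append(
            Member(sid, "WES-001", "WES-002", "unknown", affected=(i == 8))
        )
    return Pedigree(members=tuple(members), twin_pair=("WES-008", "WES-007"))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

_MODEL_ABBREV = {
    "de_novo": "DNV",
    "autosomal_recessive": "ARC",
    "autosomal_dominant": "ADC",
    "homozygous_concordant": "HOM",
}

_BASES = np.array(["A", "C", "G", "T"])
_GT = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), "./.": (None, None)}

_REGIONS = ["exonic", "intronic", "UTR", "splicing", "exonic;splicing", "intergenic"]
_REGION_P = [0.68, 0.15, 0.08, 0.03, 0.02, 0.04]
_EXONIC_CLASSES = [
    "nonsynonymous_SNV", "synonymous_SNV", "stopgain", "stoploss",
    "frameshift_insertion", "frameshift_deletion", "nonframeshift", "unknown",
]
_EXONIC_P = [0.52, 0.32, 0.03, 0.01, 0.04, 0.03, 0.03, 0.02]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _draw_site_keys(rng: np.random.Generator, n: int) -> List[Tuple[str, int]]:
    seen: Set[Tuple[str, int]] = set()
    out: List[Tuple[str, int]] = []
    while len(out) < n:
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(100_000, 200_000_000))
        if (chrom, pos) not in seen:
            seen.add((chrom, pos))
            out.append((chrom, pos))
    return out


def _ref_alt(rng: np.random.Generator) -> Tuple[str, str]:
    i = int(rng.integers(0, 4))
    j = (i + int(rng.integers(1, 4))) % 4
    return str(_BASES[i]), str(_BASES[j])


def _mendelian_child(rng: np.random.Generator, father: Tuple[int, int],
                     mother: Tuple[int, int]) -> Tuple[int, int]:
    return (father[int(rng.integers(0, 2))], mother[int(rng.integers(0, 2))])


def _gt_str(gt: Tuple[Optional[int], Optional[int]]) -> str:
    a, b = gt
    if a is None or b is None:
        return "./."
    return f"{min(a, b)}/{max(a, b)}"


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str
    tier: Optional[str]
    artifact: Optional[str]
    gene: str
    func_region: str
    exonic_class: Optional[str]
    filter_status: str
    pop_freqs: Dict[str, float]
    cadd: Optional[float]
    revel: Optional[float]
    sift: Tuple[Optional[str], Optional[float]]
    polyphen: Tuple[Optional[str], Optional[float]]
    mutation_taster: Tuple[Optional[str], Optional[float]]
    genotypes: Dict[str, str]

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def _tier_scores(rng: np.random.Generator, tier: str) -> Dict:
    """Draw pathogenicity annotations realizing a tier target."""
    if tier == "strict_pass":
        return dict(
            cadd=float(rng.uniform(21.0, 35.0)),
            revel=float(rng.uniform(0.5, 0.99)),
            sift=("D", float(rng.uniform(0, 0.02))),
            polyphen=("D", float(rng.uniform(0.95, 1.0))),
            mutation_taster=("D", float(rng.uniform(0.9, 1.0))),
        )
    if tier == "liberal_only":
        # damaging by one tool but failing a quantitative threshold
        if rng.random() < 0.5:
            cadd = float(rng.uniform(5.0, 19.5))
            revel = float(rng.uniform(0.5, 0.99))
        else:
            cadd = float(rng.uniform(21.0, 35.0))
            revel = float(rng.uniform(0.0, 0.45))
        return dict(
            cadd=cadd,
            revel=revel,
            sift=("D", float(rng.uniform(0, 0.02))),
            polyphen=("B", float(rng.uniform(0.0, 0.3))),
            mutation_taster=("N", float(rng.uniform(0.0, 0.3))),
        )
    return dict(  # fail: no tool damaging
        cadd=float(rng.uniform(0.0, 10.0)),
        revel=float(rng.uniform(0.0, 0.3)),
        sift=("T", float(rng.uniform(0.3, 1.0))),
        polyphen=("B", float(rng.uniform(0.0, 0.3))),
        mutation_taster=("N", float(rng.uniform(0.0, 0.3))),
    )


def _planted_genotypes(
    model: str, ped: Pedigree, rng: np.random.Generator
) -> Dict[str, str]:
    gts: Dict[str, str] = {}
    others = [s for s in ped.sample_ids if s != ped.affected_twin]
    if model == "de_novo":
        gts[ped.affected_twin] = "0/1"
        for s in others:
            gts[s] = "0/0"
    elif model == "autosomal_recessive":
        gts[ped.affected_twin] = "1/1"
        for p in ped.parents:
            gts[p] = "0/1"
        for s in (*ped.siblings, ped.unaffected_twin):
            gts[s] = "0/1" if rng.random() < 0.5 else "0/0"
    elif model == "autosomal_dominant":
        gts[ped.affected_twin] = "0/1"
        for s in others:
            gts[s] = "0/0"
    elif model == "homozygous_concordant":
        gts[ped.affected_twin] = "1/1"
        gts[ped.unaffected_twin] = "1/1"
        for p in ped.parents:
            gts[p] = "0/1"
        for s in ped.siblings:
            gts[s] = "0/1" if rng.random() < 0.7 else "1/1"
    else:  # panel_spike: twin-discordant but Mendelian-consistent
        gts[ped.affected_twin] = "0/1"
        gts[ped.unaffected_twin] = "0/0"
        father, mother = ped.parents
        gts[father] = "0/1"
        gts[mother] = "0/0"
        for s in ped.siblings:
            gts[s] = "0/0"
    return gts


def _simulate_sites(cfg: SimConfig, ped: Pedigree) -> List[_Site]:
    counts = cfg.planted_counts()
    n_planted = sum(counts.values()) + (1 if cfg.panel_spike_gene else 0)
    n_total = cfg.n_background_sites + n_planted

    site_rng = _rng(cfg.seed, 1)
    geno_rng = _rng(cfg.seed, 2)
    anno_rng = _rng(cfg.seed, 3)

    keys = _draw_site_keys(site_rng, n_total)
    sites: List[_Site] = []

    # -- background ---------------------------------------------------------
    freqs = np.clip(
        site_rng.beta(cfg.allele_freq_alpha, cfg.allele_freq_beta,
                      size=cfg.n_background_sites),
        cfg.allele_freq_min,
        cfg.allele_freq_max,
    )
    for i in range(cfg.n_background_sites):
        chrom, pos = keys[i]
        ref, alt = _ref_alt(site_rng)
        f = float(freqs[i])
        father_gt = tuple(int(x) for x in geno_rng.binomial(1, f, size=2))
        mother_gt = tuple(int(x) for x in geno_rng.binomial(1, f, size=2))
        gts: Dict[str, str] = {
            ped.father: _gt_str(father_gt),
            ped.mother: _gt_str(mother_gt),
        }
        for s in ped.siblings:
            gts[s] = _gt_str(_mendelian_child(geno_rng, father_gt, mother_gt))
        twin_gt = _gt_str(_mendelian_child(geno_rng, father_gt, mother_gt))
        gts[ped.affected_twin] = twin_gt
        gts[ped.unaffected_twin] = twin_gt  # MZ twins share the genome

        region = str(anno_rng.choice(_REGIONS, p=_REGION_P))
        exonic_class = (
            str(anno_rng.choice(_EXONIC_CLASSES, p=_EXONIC_P))
            if region == "exonic"
            else None
        )
        filt_draw = anno_rng.random()
        filt = "PASS" if filt_draw < 0.95 else ("LowQual" if filt_draw < 0.98 else ".")
        noise = anno_rng.uniform(0.7, 1.3, size=3)
        pop = {
            "gnomad_exome": float(np.clip(f * noise[0], 0.0, 1.0)),
            "gnomad_genome": float(np.clip(f * noise[1], 0.0, 1.0)),
            "exac": float(np.clip(f * noise[2], 0.0, 1.0)),
        }
        damaging = anno_rng.random() < 0.25
        sites.append(
            _Site(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                label="background", tier=None, artifact=None,
                gene=f"GENE{i:05d}",
                func_region=region, exonic_class=exonic_class,
                filter_status=filt, pop_freqs=pop,
                cadd=float(anno_rng.uniform(0, 40)),
                revel=float(anno_rng.uniform(0, 1)),
                sift=(("D", float(anno_rng.uniform(0, 0.05))) if damaging
                      else ("T", float(anno_rng.uniform(0.2, 1.0)))),
                polyphen=(("D", float(anno_rng.uniform(0.9, 1.0))) if damaging
                          else ("B", float(anno_rng.uniform(0, 0.4)))),
                mutation_taster=(("D", float(anno_rng.uniform(0.9, 1.0))) if damaging
                                 else ("N", float(anno_rng.uniform(0, 0.4)))),
                genotypes=gts,
            )
        )

    # -- planted ------------------------------------------------------------
    cursor = cfg.n_background_sites
    for model in MODELS:
        for idx in range(counts[model]):
            chrom, pos = keys[cursor]
            ref, alt = _ref_alt(site_rng)
            tier = cfg.tier_for(model, idx)
            scores = _tier_scores(anno_rng, tier)
            artifact = next(
                (a.kind for a in cfg.artifact_injections
                 if a.model == model and a.index == idx),
                None,
            )
            gts = _planted_genotypes(model, ped, geno_rng)
            if artifact == "no_call_others":
                gts = {
                    s: ("./." if s != ped.affected_twin else gts[s])
                    for s in gts
                }
            sites.append(
                _Site(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    label=model, tier=tier, artifact=artifact,
                    gene=f"PLT{_MODEL_ABBREV[model]}{idx:02d}",
                    func_region="exonic", exonic_class="nonsynonymous_SNV",
                    filter_status="PASS",
                    pop_freqs={"gnomad_exome": float(anno_rng.uniform(0, 1e-3))},
                    genotypes=gts,
                    **scores,
                )
            )
            cursor += 1

    if cfg.panel_spike_gene:
        chrom, pos = keys[cursor]
        ref, alt = _ref_alt(site_rng)
        scores = _tier_scores(anno_rng, "strict_pass")
        sites.append(
            _Site(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                label="panel_spike", tier="strict_pass", artifact=None,
                gene=cfg.panel_spike_gene,
                func_region="exonic", exonic_class="nonsynonymous_SNV",
                filter_status="PASS",
                pop_freqs={"gnomad_exome": float(anno_rng.uniform(0, 1e-3))},
                genotypes=_planted_genotypes("panel_spike", ped, geno_rng),
                **scores,
            )
        )

    sites.sort(key=lambda s: (chrom_sort_key(s.chrom), s.pos, s.alt))
    return sites


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

_INFO_HEADER = """\
##INFO=<ID=Gene.refGene,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=Func.refGene,Number=1,Type=String,Description="Functional region">
##INFO=<ID=ExonicFunc.refGene,Number=1,Type=String,Description="Exonic consequence">
##INFO=<ID=AAChange.refGene,Number=1,Type=String,Description="Transcript change">
##INFO=<ID=CADD_phred,Number=1,Type=Float,Description="CADD scaled score">
##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL ensemble score">
##INFO=<ID=SIFT_pred,Number=1,Type=String,Description="SIFT prediction">
##INFO=<ID=SIFT_score,Number=1,Type=Float,Description="SIFT score">
##INFO=<ID=Polyphen2_HDIV_pred,Number=1,Type=String,Description="PolyPhen-2 HDIV prediction">
##INFO=<ID=Polyphen2_HDIV_score,Number=1,Type=Float,Description="PolyPhen-2 HDIV score">
##INFO=<ID=MutationTaster_pred,Number=1,Type=String,Description="MutationTaster prediction">
##INFO=<ID=MutationTaster_score,Number=1,Type=Float,Description="MutationTaster score">
##INFO=<ID=gnomAD_exome_ALL,Number=1,Type=Float,Description="gnomAD exome allele frequency">
##INFO=<ID=gnomAD_genome_ALL,Number=1,Type=Float,Description="gnomAD genome allele frequency">
##INFO=<ID=ExAC_ALL,Number=1,Type=Float,Description="ExAC allele frequency">
##FILTER=<ID=LowQual,Description="Low quality call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">"""

_FREQ_KEYS = {
    "gnomad_exome": "gnomAD_exome_ALL",
    "gnomad_genome": "gnomAD_genome_ALL",
    "exac": "ExAC_ALL",
}


def _info_field(site: _Site) -> str:
    parts = [
        f"Gene.refGene={site.gene}",
        "Func.refGene=" + site.func_region.replace(";", "\\x3b"),
    ]
    if site.exonic_class is not None:
        parts.append(f"ExonicFunc.refGene={site.exonic_class}")
    if site.cadd is not None:
        parts.append(f"CADD_phred={site.cadd:.3f}")
    if site.revel is not None:
        parts.append(f"REVEL={site.revel:.3f}")
    for name, (pred, score) in (
        ("SIFT", site.sift),
        ("Polyphen2_HDIV", site.polyphen),
        ("MutationTaster", site.mutation_taster),
    ):
        if pred is not None:
            parts.append(f"{name}_pred={pred}")
        if score is not None:
            parts.append(f"{name}_score={score:.3f}")
    for source, freq in site.pop_freqs.items():
        parts.append(f"{_FREQ_KEYS[source]}={freq:.6f}")
    return ";".join(parts)


def _write_vcf(sites: Sequence[_Site], samples: Sequence[str], path: Path) -> None:
    contigs = sorted({s.chrom for s in sites}, key=chrom_sort_key)
    lines = ["##fileformat=VCFv4.2", "##source=twinvar-simulate"]
    lines += [f"##contig=<ID={c},length=250000000>" for c in contigs]
    lines.append(_INFO_HEADER)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for s in sites:
        row = [
            s.chrom, str(s.pos), ".", s.ref, s.alt, "100",
            s.filter_status, _info_field(s), "GT",
        ] + [s.genotypes[sid] for sid in samples]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _simulate_pileup(
    sites: Sequence[_Site],
    samples: Sequence[str],
    affected: str,
    mean_depth: float,
    rng: np.random.Generator,
) -> Dict[VariantKey, Dict[str, ReviewEvidence]]:
    """Read evidence for planted/spiked sites, honouring artifacts."""
    out: Dict[VariantKey, Dict[str, ReviewEvidence]] = {}
    for s in sites:
        if s.label == "background":
            continue
        per_sample: Dict[str, ReviewEvidence] = {}
        for sid in samples:
            gt = s.genotypes[sid]
            if s.artifact == "low_depth":
                depth = int(rng.integers(10, 20))
            elif gt == "./.":
                depth = int(rng.poisson(8))
            else:
                depth = max(8, int(rng.poisson(mean_depth)))
            if s.artifact == "low_aaf_carrier" and sid == affected:
                depth = int(rng.integers(40, 50))
                alt = max(1, int(round(0.09 * depth)))
            elif gt == "1/1":
                alt = int(rng.binomial(depth, 0.98))
            elif gt == "0/1":
                alt = int(rng.binomial(depth, 0.5))
                alt = min(max(alt, int(0.3 * depth)), int(0.7 * depth)) if depth >= 10 else alt
            elif gt == "./.":
                alt = int(rng.binomial(depth, 0.5)) if depth else 0
            else:
                alt = int(rng.binomial(depth, 0.002))
            alt = min(alt, depth)
            ref_reads = depth - alt
            if s.artifact == "strand_biased_alt" and sid == affected:
                alt = max(alt, 3)
                depth = max(depth, alt)
                ref_reads = depth - alt
                alt_fwd, alt_rev = alt, 0
            else:
                alt_fwd = int(rng.binomial(alt, 0.5)) if alt else 0
                alt_rev = alt - alt_fwd
            ref_fwd = int(rng.binomial(ref_reads, 0.5)) if ref_reads else 0
            per_sample[sid] = ReviewEvidence(
                sample_id=sid, depth=depth, alt_reads=alt,
                alt_fwd=alt_fwd, alt_rev=alt_rev,
                ref_fwd=ref_fwd, ref_rev=ref_reads - ref_fwd,
            )
        out[s.key] = per_sample
    return out


def _write_qc(samples: Sequence[str], rng: np.random.Generator, path: Path) -> None:
    lines = ["sample\tmean_coverage\tpct_ge_20x\tpct_ge_50x\taligned_reads\tuniformity"]
    for sid in samples:
        mean_cov = rng.normal(160.0, 15.0)
        pct20 = rng.uniform(94.5, 95.2)
        pct50 = pct20 - rng.uniform(2.0, 4.0)
        reads = int(rng.normal(7.0e7, 6.0e6))
        unif = rng.uniform(94.0, 94.3)
        lines.append(
            f"{sid}\t{mean_cov:.2f}\t{pct20:.2f}\t{pct50:.2f}\t{reads}\t{unif:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_truth(sites: Sequence[_Site], samples: Sequence[str], path: Path) -> None:
    header = ["chrom", "pos", "ref", "alt", "label", "tier", "artifact", "gene"] + list(samples)
    lines = ["\t".join(header)]
    for s in sites:
        lines.append(
            "\t".join(
                [
                    s.chrom, str(s.pos), s.ref, s.alt, s.label,
                    s.tier or ".", s.artifact or ".", s.gene,
                ]
                + [s.genotypes[sid] for sid in samples]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: SimConfig, ped: Pedigree, out_dir: Union[str, Path]
) -> SimBundle:
    """Generate one cohort bundle (VCF, pileup TSV, QC TSV, truth TSV, PED).

    Identical config and seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = list(ped.sample_ids)

    sites = _simulate_sites(cfg, ped)

    vcf_path = out / "cohort.vcf"
    _write_vcf(sites, samples, vcf_path)

    pileup_path = out / "pileup_summary.tsv"
    pileup = _simulate_pileup(
        sites, samples, ped.affected_twin, cfg.mean_site_depth, _rng(cfg.seed, 4)
    )
    write_pileup_summary(pileup, pileup_path)

    qc_path = out / "qc_metrics.tsv"
    _write_qc(samples, _rng(cfg.seed, 5), qc_path)

    truth_path = out / "truth.tsv"
    _write_truth(sites, samples, truth_path)

    ped_path = out / "family.ped"
    write_pedigree(ped, ped_path)

    truth_records = tuple(
        TruthRecord(
            key=s.key, label=s.label, tier=s.tier, artifact=s.artifact,
            genotypes=dict(s.genotypes), gene=s.gene,
        )
        for s in sites
    )
    exempt = frozenset(
        s.key for s in sites if s.label in ("de_novo", "autosomal_dominant")
    )
    return SimBundle(
        vcf=vcf_path, pileup=pileup_path, qc=qc_path, truth=truth_path,
        ped=ped_path, truth_records=truth_records, mendelian_exempt=exempt,
    )


def mendelian_check(
    variants,
    ped: Pedigree,
    exempt: frozenset = frozenset(),
) -> int:
    """Count offspring genotypes impossible under Mendelian transmission.

    ``variants`` is an iterable of AnnotatedVariant.  Sites in ``exempt``
    (e.g. planted de novo patterns) are skipped; genotypes involving missing
    alleles cannot be judged and are skipped too.
    """
    violations = 0
    by_id = {m.sample_id: m for m in ped.members}
    for v in variants:
        if v.key in exempt:
            continue
        for m in ped.members:
            if m.father_id is None:
                continue
            child = v.genotypes.get(m.sample_id)
            father = v.genotypes.get(m.father_id)
            mother = v.genotypes.get(m.mother_id)
            if child is None or father is None or mother is None:
                continue
            if any(a is None for gt in (child, father, mother) for a in gt.alleles):
                continue
            ca, cb = child.alleles
            ok = any(
                {ca, cb} == {pa, ma} or (ca == pa and cb == ma) or (ca == ma and cb == pa)
                for pa in father.alleles
                for ma in mother.alleles
            )
            if not ok:
                violations += 1
    return violations
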