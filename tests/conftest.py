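"""Shared fixtures: the eight-member study pedigree and one simulated cohort."""

from __future__ import annotations

from typing import Dict, Optional

import pytest

from twinvar.core import (
    AnnotatedVariant,
    AnnotationBundle,
    GenotypeCall,
    PathogenicityScores,
    ToolCall,
    VariantKey,
)
from twinvar.simulate import ArtifactSpec, SimConfig, simulate_cohort, study_pedigree
from twinvar.vcf_io import read_cohort

_GT = {
    "0/0": (0, 0),
    "0/1": (0, 1),
    "1/0": (1, 0),
    "1/1": (1, 1),
    "./.": (None, None),
    "./1": (None, 1),
    "0/.": (0, None),
}


def make_variant(
    genotypes: Dict[str, str],
    samples=None,
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
    filter_status: str = "PASS",
    gene: str = "GENE1",
    func_region: Optional[str] = "exonic",
    exonic_class: Optional[str] = "nonsynonymous_SNV",
    scores: PathogenicityScores = PathogenicityScores(
        cadd_phred=25.0, revel=0.8, sift=ToolCall("D", 0.01)
    ),
    pop_freqs=None,
) -> AnnotatedVariant:
    """Build a variant from genotype strings; samples not listed in
    ``genotypes`` default to 0/0."""
    all_samples = samples if samples is not None else list(genotypes)
    calls = {
        sid: GenotypeCall(sample_id=sid, alleles=_GT[genotypes.get(sid, "0/0")])
        for sid in all_samples
    }
    return AnnotatedVariant(
        key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
        filter_status=filter_status,
        bundle=AnnotationBundle(
            gene=gene,
            func_region=func_region,
            exonic_class=exonic_class,
            pop_freqs=pop_freqs or {},
            scores=scores,
        ),
        genotypes=calls,
    )


@pytest.fixture(scope="session")
def ped():
    return study_pedigree()


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory, ped):
    cfg = SimConfig(
        seed=7,
        n_background_sites=400,
        panel_spike_gene="TBX6",
        artifact_injections=(
            ArtifactSpec("de_novo", 1, "low_aaf_carrier"),
            ArtifactSpec("autosomal_recessive", 1, "no_call_others"),
        ),
    )
    return simulate_cohort(cfg, ped, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def sim_variants(sim_bundle, ped):
    return read_cohort(sim_bundle.vcf, expected_samples=ped.sample_ids)
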