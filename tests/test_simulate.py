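"""Simulator contracts: determinism, Mendelian consistency, twin identity,
tier-target realization, and screen recovery of planted variants."""

import numpy as np
import pytest

from conftest import make_variant
from twinvar.core import GenotypeClass
from twinvar.filtering import liberal_tier, strict_tier
from twinvar.inheritance import ModelConfig, screen_cohort
from twinvar.simulate import (
    ArtifactSpec,
    SimConfig,
    mendelian_check,
    simulate_cohort,
    study_pedigree,
)
from twinvar.vcf_io import read_cohort


class TestConfigValidation:
    def test_planted_exceeding_background_context(self):
        with pytest.raises(ValueError, match="background"):
            SimConfig(seed=1, n_background_sites=3, n_de_novo=4)

    def test_unknown_artifact_kind(self):
        with pytest.raises(ValueError, match="artifact"):
            ArtifactSpec("de_novo", 0, "phasing_error")

    def test_artifact_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            SimConfig(
                seed=1,
                n_de_novo=1,
                artifact_injections=(ArtifactSpec("de_novo", 5, "low_depth"),),
            )

    def test_tier_target_length_mismatch(self):
        with pytest.raises(ValueError, match="tier"):
            SimConfig(seed=1, n_de_novo=2, tier_targets={"de_novo": ["strict_pass"]})


def test_same_seed_byte_identical_outputs(tmp_path, ped):
    cfg = SimConfig(seed=11, n_background_sites=120, panel_spike_gene="TBX6")
    a = simulate_cohort(cfg, ped, tmp_path / "a")
    b = simulate_cohort(cfg, ped, tmp_path / "b")
    for attr in ("vcf", "pileup", "qc", "truth", "ped"):
        assert getattr(a, attr).read_bytes() == getattr(b, attr).read_bytes(), attr


def test_different_seed_differs(tmp_path, ped):
    a = simulate_cohort(SimConfig(seed=1, n_background_sites=50), ped, tmp_path / "a")
    b = simulate_cohort(SimConfig(seed=2, n_background_sites=50), ped, tmp_path / "b")
    assert a.vcf.read_bytes() != b.vcf.read_bytes()


class TestCohortStructure:
    def test_twins_identical_at_background_sites(self, sim_bundle, ped):
        for t in sim_bundle.truth_records:
            if t.label == "background":
                assert t.genotypes[ped.affected_twin] == t.genotypes[ped.unaffected_twin]

    def test_mendelian_consistency_outside_exempt(self, sim_variants, ped, sim_bundle):
        assert mendelian_check(sim_variants, ped, sim_bundle.mendelian_exempt) == 0

    def test_hand_built_violation_counted(self, ped):
        v = make_variant(
            {"WES-008": "1/1"}, samples=ped.sample_ids  # parents default 0/0
        )
        assert mendelian_check([v], ped) == 1

    def test_empty_cohort_zero_violations(self, ped):
        assert mendelian_check([], ped) == 0

    def test_vcf_round_trip_matches_truth_genotypes(self, sim_bundle, sim_variants, ped):
        truth = {t.key: t for t in sim_bundle.truth_records}
        cls_of = {"0/0": GenotypeClass.HOM_REF, "0/1": GenotypeClass.HET,
                  "1/1": GenotypeClass.HOM_ALT, "./.": GenotypeClass.NO_CALL}
        assert len(sim_variants) == len(truth)
        for v in sim_variants:
            t = truth[v.key]
            for sid in ped.sample_ids:
                assert v.genotype_class(sid) == cls_of[t.genotypes[sid]], (v.key, sid)


def test_tier_targets_realized(tmp_path, ped):
    """Planted pathogenicity tiers close the loop with the filter module:
    strict_pass passes both tiers, liberal_only passes only the liberal one,
    fail passes neither."""
    cfg = SimConfig(
        seed=5,
        n_background_sites=60,
        n_de_novo=3,
        n_autosomal_recessive=0,
        n_autosomal_dominant=3,
        n_homozygous_concordant=0,
        tier_targets={
            "de_novo": ["strict_pass", "liberal_only", "fail"],
            "autosomal_dominant": ["strict_pass", "liberal_only", "fail"],
        },
    )
    bundle = simulate_cohort(cfg, ped, tmp_path)
    variants = {v.key: v for v in read_cohort(bundle.vcf, expected_samples=ped.sample_ids)}
    checked = 0
    for t in bundle.truth_records:
        if t.tier is None:
            continue
        scores = variants[t.key].bundle.scores
        lib, strict = liberal_tier(scores), strict_tier(scores)
        if t.tier == "strict_pass":
            assert lib and strict
        elif t.tier == "liberal_only":
            assert lib and not strict
        else:
            assert not lib and not strict
        checked += 1
    assert checked == 6


def test_planted_variants_recovered_by_their_screens(tmp_path, ped):
    """Clean planted sites are admitted by exactly the screens their genotype
    pattern satisfies, and never by a conflicting screen."""
    cfg = SimConfig(seed=3, n_background_sites=200)
    bundle = simulate_cohort(cfg, ped, tmp_path)
    variants = read_cohort(bundle.vcf, expected_samples=ped.sample_ids)
    screened = screen_cohort(variants, ped, ModelConfig())
    admitted = {m: {c.variant.key for c in cands} for m, cands in screened.items()}
    for t in bundle.truth_records:
        if t.label == "background" or t.artifact is not None:
            continue
        if t.label == "de_novo":
            assert t.key in admitted["de_novo"]
            assert t.key not in admitted["autosomal_recessive"]
            assert t.key not in admitted["homozygous_screen"]
        elif t.label == "autosomal_recessive":
            assert t.key in admitted["autosomal_recessive"]
            assert t.key not in admitted["de_novo"]
            assert t.key not in admitted["autosomal_dominant"]
        elif t.label == "autosomal_dominant":
            assert t.key in admitted["autosomal_dominant"]
            assert t.key not in admitted["autosomal_recessive"]
            assert t.key not in admitted["homozygous_screen"]
        elif t.label == "homozygous_concordant":
            assert t.key in admitted["homozygous_screen"]
            assert t.key not in admitted["de_novo"]
            assert t.key not in admitted["autosomal_dominant"]
            assert t.key not in admitted["autosomal_recessive"]


def test_background_allele_frequencies_recovered(tmp_path, ped):
    """Parameter recovery: the pooled founder allele frequency over many
    background sites matches the mean of the truncated Beta(0.5, 5) site
    frequency distribution within sampling error."""
    cfg = SimConfig(
        seed=13, n_background_sites=4000,
        n_de_novo=0, n_autosomal_recessive=0, n_autosomal_dominant=0,
        n_homozygous_concordant=0,
    )
    bundle = simulate_cohort(cfg, ped, tmp_path)
    alt = {"0/0": 0, "0/1": 1, "1/1": 2}
    founder_alleles = [
        alt[t.genotypes[sid]]
        for t in bundle.truth_records
        for sid in ped.parents
    ]
    observed = np.mean(founder_alleles) / 2.0
    rng = np.random.default_rng(99)
    expected = float(
        np.mean(np.clip(rng.beta(0.5, 5.0, size=200_000), 1e-4, 0.5))
    )
    # SE of the observed mean over 8000 founder allele pairs is ~0.003
    assert observed == pytest.approx(expected, abs=0.012)


def test_no_call_artifact_reaches_vcf(tmp_path, ped):
    cfg = SimConfig(
        seed=21, n_background_sites=40, n_de_novo=0, n_autosomal_dominant=0,
        n_homozygous_concordant=0, n_autosomal_recessive=1,
        artifact_injections=(ArtifactSpec("autosomal_recessive", 0, "no_call_others"),),
    )
    bundle = simulate_cohort(cfg, ped, tmp_path)
    t = next(t for t in bundle.truth_records if t.artifact == "no_call_others")
    variants = {v.key: v for v in read_cohort(bundle.vcf)}
    v = variants[t.key]
    assert v.genotype_class(ped.affected_twin) == GenotypeClass.HOM_ALT
    for sid in ped.sample_ids:
        if sid != ped.affected_twin:
            assert v.genotype_class(sid) == GenotypeClass.NO_CALL
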