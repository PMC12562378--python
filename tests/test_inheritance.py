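"""Genotype-model screens and twin concordance on the study pedigree."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant
from twinvar.inheritance import (
    NOTE_CONCORDANT_TWIN,
    NOTE_NO_CALL,
    NOTE_PENETRANCE,
    ModelConfig,
    autosomal_dominant_screen,
    autosomal_recessive_screen,
    de_novo_screen,
    homozygous_screen,
    screen_cohort,
    twin_concordance,
)

PERMISSIVE = ModelConfig()
STRICT = ModelConfig(no_call_policy="strict")

AFF, UNAFF = "WES-008", "WES-007"
FATHER, MOTHER = "WES-001", "WES-002"
SIBS = ("WES-003", "WES-004", "WES-005", "WES-006")


def fam_variant(ped, gts, **kw):
    return make_variant(gts, samples=ped.sample_ids, **kw)


class TestDeNovo:
    def test_affected_only_het(self, ped):
        v = fam_variant(ped, {AFF: "0/1"})
        assert de_novo_screen(v, ped, PERMISSIVE).admitted

    def test_no_call_elsewhere_permissive_vs_strict(self, ped):
        """A hom_alt affected twin with ./. in everyone else survives the
        permissive screen (flagged) and is excluded by the strict one."""
        gts = {sid: "./." for sid in ped.sample_ids}
        gts[AFF] = "1/1"
        v = fam_variant(ped, gts)
        res = de_novo_screen(v, ped, PERMISSIVE)
        assert res.admitted and NOTE_NO_CALL in res.notes
        assert not de_novo_screen(v, ped, STRICT).admitted

    def test_shared_with_unaffected_twin_rejected(self, ped):
        v = fam_variant(ped, {AFF: "0/1", UNAFF: "0/1"})
        assert not de_novo_screen(v, ped, PERMISSIVE).admitted

    def test_parent_carrier_rejected(self, ped):
        v = fam_variant(ped, {AFF: "0/1", FATHER: "0/1"})
        assert not de_novo_screen(v, ped, PERMISSIVE).admitted

    def test_missing_member_genotype_is_hard_error(self, ped):
        v = make_variant({AFF: "0/1"}, samples=[AFF])  # others absent entirely
        with pytest.raises(KeyError):
            de_novo_screen(v, ped, PERMISSIVE)


class TestAutosomalRecessive:
    def test_literal_pattern(self, ped):
        v = fam_variant(
            ped,
            {AFF: "1/1", FATHER: "0/1", MOTHER: "0/1",
             SIBS[0]: "0/1", UNAFF: "0/1"},
        )
        assert autosomal_recessive_screen(v, ped, PERMISSIVE).admitted

    def test_hom_alt_unaffected_twin_rejected(self, ped):
        v = fam_variant(
            ped, {AFF: "1/1", FATHER: "0/1", MOTHER: "0/1", UNAFF: "1/1"}
        )
        assert not autosomal_recessive_screen(v, ped, PERMISSIVE).admitted

    def test_non_carrier_parent_rejected(self, ped):
        v = fam_variant(ped, {AFF: "1/1", FATHER: "0/0", MOTHER: "0/1"})
        assert not autosomal_recessive_screen(v, ped, PERMISSIVE).admitted

    def test_hom_alt_sibling_rejected(self, ped):
        v = fam_variant(
            ped,
            {AFF: "1/1", FATHER: "0/1", MOTHER: "0/1", SIBS[1]: "1/1"},
        )
        assert not autosomal_recessive_screen(v, ped, PERMISSIVE).admitted


class TestAutosomalDominant:
    def test_literal_pattern(self, ped):
        v = fam_variant(ped, {AFF: "0/1"})
        assert autosomal_dominant_screen(v, ped, PERMISSIVE).admitted

    def test_het_parent_requires_penetrance_flag(self, ped):
        v = fam_variant(ped, {AFF: "0/1", FATHER: "0/1"})
        assert not autosomal_dominant_screen(v, ped, PERMISSIVE).admitted
        cfg = ModelConfig(incomplete_penetrance=True)
        res = autosomal_dominant_screen(v, ped, cfg)
        assert res.admitted and NOTE_PENETRANCE in res.notes

    def test_two_het_parents_rejected_even_with_penetrance(self, ped):
        v = fam_variant(ped, {AFF: "0/1", FATHER: "0/1", MOTHER: "0/1"})
        cfg = ModelConfig(incomplete_penetrance=True)
        assert not autosomal_dominant_screen(v, ped, cfg).admitted

    def test_het_sibling_rejected(self, ped):
        v = fam_variant(ped, {AFF: "0/1", SIBS[2]: "0/1"})
        assert not autosomal_dominant_screen(v, ped, PERMISSIVE).admitted


class TestHomozygousScreen:
    def test_concordant_twin_noted(self, ped):
        v = fam_variant(
            ped, {AFF: "1/1", UNAFF: "1/1", FATHER: "0/1", MOTHER: "0/1"}
        )
        res = homozygous_screen(v, ped, PERMISSIVE)
        assert res.admitted and NOTE_CONCORDANT_TWIN in res.notes

    def test_discordant_admitted_without_note(self, ped):
        v = fam_variant(ped, {AFF: "1/1", FATHER: "0/1", MOTHER: "0/1"})
        res = homozygous_screen(v, ped, PERMISSIVE)
        assert res.admitted and NOTE_CONCORDANT_TWIN not in res.notes

    def test_het_affected_rejected(self, ped):
        v = fam_variant(ped, {AFF: "0/1"})
        assert not homozygous_screen(v, ped, PERMISSIVE).admitted


def test_non_autosomal_sites_excluded_from_screens(ped):
    v = fam_variant(ped, {AFF: "0/1"}, chrom="chrX")
    assert not de_novo_screen(v, ped, PERMISSIVE).admitted
    assert de_novo_screen(
        v, ped, ModelConfig(autosomes_only=False)
    ).admitted


class TestTwinConcordance:
    def test_all_shared(self, ped):
        vs = [
            fam_variant(ped, {AFF: "0/1", UNAFF: "0/1"}, pos=i + 1)
            for i in range(5)
        ]
        assert twin_concordance(vs, ped).percent_shared == 100.0

    def test_all_affected_only(self, ped):
        vs = [fam_variant(ped, {AFF: "0/1"}, pos=i + 1) for i in range(5)]
        s = twin_concordance(vs, ped)
        assert s.percent_shared == 0.0
        assert s.unique_to_affected == 5

    def test_98_of_100_shared(self, ped):
        vs = [
            fam_variant(ped, {AFF: "0/1", UNAFF: "0/1"}, pos=i + 1)
            for i in range(98)
        ]
        vs.append(fam_variant(ped, {AFF: "0/1"}, pos=200))
        vs.append(fam_variant(ped, {UNAFF: "1/1"}, pos=201))
        s = twin_concordance(vs, ped)
        assert s.shared_count == 98
        assert s.percent_shared == pytest.approx(98.0)

    def test_absent_from_both_twins_ignored(self, ped):
        vs = [fam_variant(ped, {FATHER: "0/1"}, pos=1)]
        s = twin_concordance(vs, ped)
        assert (s.shared_count, s.unique_to_affected, s.unique_to_unaffected) == (0, 0, 0)
        assert s.percent_shared == 0.0


# -- properties --------------------------------------------------------------

GT_CHOICES = ["0/0", "0/1", "1/1", "./."]
genotype_maps = st.fixed_dictionaries(
    {
        sid: st.sampled_from(GT_CHOICES)
        for sid in (FATHER, MOTHER, *SIBS, UNAFF, AFF)
    }
)


@given(genotype_maps)
@settings(max_examples=500, deadline=None)
def test_dominant_and_recessive_mutually_exclusive(ped, gts):
    """The AD screen needs a het proband, the AR screen a hom_alt one; no
    genotype vector can satisfy both."""
    v = fam_variant(ped, gts)
    for cfg in (PERMISSIVE, STRICT, ModelConfig(incomplete_penetrance=True)):
        assert not (
            autosomal_dominant_screen(v, ped, cfg).admitted
            and autosomal_recessive_screen(v, ped, cfg).admitted
        )


@given(st.lists(genotype_maps, max_size=25))
@settings(max_examples=100, deadline=None)
def test_strict_candidates_subset_of_permissive(ped, cohort_gts):
    variants = [fam_variant(ped, gts, pos=i + 1) for i, gts in enumerate(cohort_gts)]
    strict = screen_cohort(variants, ped, STRICT)
    permissive = screen_cohort(variants, ped, PERMISSIVE)
    for model in strict:
        s_keys = {c.variant.key for c in strict[model]}
        p_keys = {c.variant.key for c in permissive[model]}
        assert s_keys <= p_keys


@given(st.lists(genotype_maps, max_size=15), st.randoms())
@settings(max_examples=50, deadline=None)
def test_screens_order_independent(ped, cohort_gts, rnd):
    variants = [fam_variant(ped, gts, pos=i + 1) for i, gts in enumerate(cohort_gts)]
    shuffled = list(variants)
    rnd.shuffle(shuffled)
    a = screen_cohort(variants, ped)
    b = screen_cohort(shuffled, ped)
    for model in a:
        assert {c.variant.key for c in a[model]} == {c.variant.key for c in b[model]}
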