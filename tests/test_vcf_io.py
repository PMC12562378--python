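"""VCF reading, multiallelic decomposition, dialect mapping, candidate tables."""

import pytest

from twinvar import datasets
from twinvar.core import GenotypeClass
from twinvar.filtering import strict_tier
from twinvar.vcf_io import (
    AnnotationDialect,
    VcfFormatError,
    chrom_sort_key,
    read_candidates,
    read_cohort,
    write_candidates,
)

SAMPLES = [f"S{i}" for i in range(1, 9)]

_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=250000000>
##contig=<ID=chr2,length=250000000>
##INFO=<ID=Gene.refGene,Number=1,Type=String,Description="g">
##INFO=<ID=Func.refGene,Number=1,Type=String,Description="f">
##INFO=<ID=ExonicFunc.refGene,Number=1,Type=String,Description="e">
##INFO=<ID=CADD_phred,Number=1,Type=Float,Description="c">
##INFO=<ID=REVEL,Number=1,Type=Float,Description="r">
##INFO=<ID=gnomAD_exome_ALL,Number=1,Type=Float,Description="af">
##FILTER=<ID=LowQual,Description="lq">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t""" + "\t".join(SAMPLES)


def _vcf(tmp_path, records):
    p = tmp_path / "test.vcf"
    p.write_text(_HEADER + "\n" + "\n".join(records) + "\n")
    return p


def _record(chrom="chr1", pos=100, ref="A", alt="G", filt="PASS",
            info="Gene.refGene=GENE1", gts=None):
    gts = gts or ["0/0"] * 8
    return "\t".join(
        [chrom, str(pos), ".", ref, alt, "50", filt, info, "GT"] + gts
    )


class TestReadCohort:
    def test_minimal_biallelic_record(self, tmp_path):
        gts = ["0/0"] * 7 + ["0/1"]
        vcf = _vcf(tmp_path, [_record(gts=gts)])
        (v,) = read_cohort(vcf, expected_samples=SAMPLES)
        classes = [v.genotype_class(s) for s in SAMPLES]
        assert classes.count(GenotypeClass.HOM_REF) == 7
        assert classes.count(GenotypeClass.HET) == 1
        assert v.filter_status == "PASS"

    def test_annovar_scores_mapped(self, tmp_path):
        info = "Gene.refGene=STOX1;Func.refGene=exonic;" \
               "ExonicFunc.refGene=nonsynonymous_SNV;CADD_phred=26.4;REVEL=0.535"
        vcf = _vcf(tmp_path, [_record(info=info)])
        (v,) = read_cohort(vcf)
        assert v.bundle.scores.cadd_phred == pytest.approx(26.4)
        assert v.bundle.scores.revel == pytest.approx(0.535)
        assert v.bundle.gene == "STOX1"
        assert v.bundle.exonic_class == "nonsynonymous_SNV"

    def test_absent_info_fields_become_absent_not_defaults(self, tmp_path):
        vcf = _vcf(tmp_path, [_record(info="Gene.refGene=G1")])
        (v,) = read_cohort(vcf)
        s = v.bundle.scores
        assert s.cadd_phred is None and s.revel is None
        assert s.sift.category is None
        assert v.bundle.pop_freqs == {}

    def test_filter_dot_distinct_from_pass(self, tmp_path):
        vcf = _vcf(tmp_path, [_record(pos=1, filt="."),
                              _record(pos=2, filt="LowQual"),
                              _record(pos=3, filt="PASS")])
        v1, v2, v3 = read_cohort(vcf)
        assert v1.filter_status == "."
        assert v2.filter_status == "LowQual"
        assert v3.filter_status == "PASS"

    def test_exonic_splicing_escape_decoded(self, tmp_path):
        vcf = _vcf(tmp_path, [_record(info="Func.refGene=exonic\\x3bsplicing")])
        (v,) = read_cohort(vcf)
        assert v.bundle.func_region == "exonic;splicing"
        assert v.bundle.regions == {"exonic", "splicing"}

    def test_missing_expected_sample_named_in_error(self, tmp_path):
        vcf = _vcf(tmp_path, [_record()])
        with pytest.raises(VcfFormatError, match="S9"):
            read_cohort(vcf, expected_samples=SAMPLES + ["S9"])


class TestMultiallelicDecomposition:
    def test_biallelic_split_and_allele_remap(self, tmp_path):
        gts = ["0/0", "0/1", "0/2", "1/2", "1/1", "2/2", "./.", "0/0"]
        vcf = _vcf(tmp_path, [_record(alt="G,T", gts=gts)])
        va, vt = read_cohort(vcf, expected_samples=SAMPLES)
        assert (va.key.alt, vt.key.alt) == ("G", "T")
        # against alt G: allele 1 -> 1, allele 2 -> missing
        assert va.genotypes["S2"].alleles == (0, 1)
        assert va.genotypes["S3"].alleles == (0, None)
        assert va.genotypes["S4"].alleles == (1, None)
        assert va.genotypes["S5"].alleles == (1, 1)
        assert va.genotypes["S6"].alleles == (None, None)
        # against alt T the roles swap
        assert vt.genotypes["S2"].alleles == (0, None)
        assert vt.genotypes["S3"].alleles == (0, 1)
        assert vt.genotypes["S4"].alleles == (None, 1)
        assert vt.genotypes["S6"].alleles == (1, 1)
        # a 1/2 genotype must never classify hom_ref for either alt
        assert va.genotype_class("S4") == GenotypeClass.NO_CALL
        assert vt.genotype_class("S4") == GenotypeClass.NO_CALL

    def test_decomposition_conserves_alt_count(self, tmp_path):
        records = [
            _record(pos=10, alt="G"),
            _record(pos=20, alt="G,T"),
            _record(pos=30, alt="C,G,T", ref="A"),
        ]
        out = read_cohort(_vcf(tmp_path, records))
        assert len(out) == 1 + 2 + 3


class TestDialect:
    def test_override_from_file(self, tmp_path):
        cfg = tmp_path / "dialect.cfg"
        cfg.write_text("cadd_phred=MyCADD\n# comment\n")
        d = AnnotationDialect.from_file(cfg)
        assert d.field_name_map["cadd_phred"] == "MyCADD"
        assert d.field_name_map["revel"] == "REVEL"  # default retained


class TestCandidateTables:
    def test_empty_set_writes_header_only(self, tmp_path):
        out = tmp_path / "cands.tsv"
        write_candidates([], out, samples=["A", "B"])
        lines = out.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("Gene\tChr\tPos")

    def test_round_trip_preserves_keys_genotypes_scores(self, sim_variants, ped, tmp_path):
        from twinvar.filtering import apply_funnel

        _, survivors = apply_funnel(sim_variants)
        subset = survivors["strict"]
        assert subset, "fixture must yield strict survivors"
        out = tmp_path / "cands.tsv"
        write_candidates(subset, out, samples=ped.sample_ids)
        back = read_candidates(out)
        assert len(back) == len(subset)
        by_key = {c.variant.key: c.variant for c in back}
        for v in subset:
            w = by_key[v.key]
            for sid in ped.sample_ids:
                assert w.genotype_class(sid) == v.genotype_class(sid)
            assert w.bundle.scores.cadd_phred == pytest.approx(
                v.bundle.scores.cadd_phred, abs=5e-4
            )
            assert w.bundle.scores.revel == pytest.approx(
                v.bundle.scores.revel, abs=5e-4
            )
            assert w.bundle.scores.sift.category == v.bundle.scores.sift.category

    def test_published_rows_survive_round_trip(self, tmp_path):
        """The five de novo candidate rows keep every score field through a
        write/read cycle."""
        cands = datasets.load_denovo_candidates()
        out = tmp_path / "denovo.tsv"
        write_candidates([c.as_variant() for c in cands], out, samples=[])
        back = read_candidates(out)
        assert len(back) == 5
        by_gene = {c.variant.bundle.gene: c.variant.bundle.scores for c in back}
        for c in cands:
            s = by_gene[c.gene]
            assert s.cadd_phred == pytest.approx(c.scores.cadd_phred)
            assert s.revel == pytest.approx(c.scores.revel)
            assert s.sift.category == c.scores.sift.category
            assert s.polyphen2_hdiv.category == c.scores.polyphen2_hdiv.category
            assert s.mutation_taster.category == c.scores.mutation_taster.category
            assert strict_tier(s) == strict_tier(c.scores)

    def test_rows_in_natural_chromosome_order(self, ped, sim_variants, tmp_path):
        out = tmp_path / "all.tsv"
        write_candidates(sim_variants, out, samples=ped.sample_ids)
        rows = [l.split("\t") for l in out.read_text().splitlines()[1:]]
        keys = [(chrom_sort_key(r[1]), int(r[2])) for r in rows]
        assert keys == sorted(keys)


def test_chrom_natural_order():
    chroms = ["chr10", "chr2", "chrX", "chr1", "chrM", "chr22"]
    assert sorted(chroms, key=chrom_sort_key) == [
        "chr1", "chr2", "chr10", "chr22", "chrX", "chrM",
    ]
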