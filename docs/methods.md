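# Methods

## Setting and model

The package analyses a nuclear family with two genotyped founder parents, any
number of unaffected siblings, and a monozygotic twin pair of which exactly
one member is affected.  Because MZ twins are genetically identical at
conception, a coding variant explaining the phenotype discordance must be
absent from the co-twin — de novo or postzygotic — or must segregate under a
model with incomplete penetrance.  The pipeline therefore treats the family
as a constraint system over per-sample genotypes at each biallelic site and
reports the variants compatible with each inheritance hypothesis, together
with the read-level evidence for the underlying calls.

Variants are consumed post-annotation: population frequencies (gnomAD
exome/genome, ExAC), functional region and exonic consequence, and five
in-silico pathogenicity sources (CADD, REVEL, SIFT, PolyPhen-2 HDIV,
MutationTaster) are parsed from INFO fields via a configurable dialect map
(defaults follow ANNOVAR table-output naming).  The package never recomputes
these scores.

## Filtering funnel

Stages, in order, each recording a survivor count:

| stage | rule | default |
|---|---|---|
| quality | VCF FILTER equals `PASS`; `.` counts as not-PASS | on |
| rarity | max over *present* population frequencies ≤ threshold; all-absent → keep | 0.01 |
| consequence | region ∩ {exonic, splicing} ≠ ∅ and protein-altering class (or pure splicing with absent class) | — |
| liberal tier | damaging by ≥ 1 of SIFT {D}, PolyPhen-2 {D, P}, MutationTaster {D, A} | — |
| strict tier | liberal **and** CADD > 20 (strict) **and** REVEL ≥ 0.5 (inclusive) | — |

Design choices worth stating explicitly:

* The strict tier is *cumulative* on the liberal one ("additional
  thresholds"), so strict survivors are a subset of liberal survivors by
  construction.
* The asymmetric bounds (CADD strictly greater, REVEL inclusive) are what the
  published survivor tables require: a candidate at REVEL exactly 0.5
  survives, one at CADD exactly 20 does not.
* PolyPhen-2 "possibly damaging" (P) counts as damaging — a P-classified
  candidate survived liberal filtering in the index study — while
  MutationTaster "polymorphism" (P) does not; its damaging classes are D and
  A (disease-causing / automatic).
* Absent annotations never pass a threshold, and the rarity rule keeps
  variants absent from every frequency database (novel variants are the
  interesting ones in a de novo screen).
* The MAF rule takes the maximum over present sources ("population
  databases", plural, read conservatively).

## Genotype-model screens

All screens ignore phasing, operate on genotype classes (hom_ref / het /
hom_alt / no_call; half-calls are no_call), and by default consider
autosomes only.

* **de novo** — affected twin het *or* hom_alt (a 1/1 proband with 0/0
  relatives is still a variant unique to the proband), every other member
  hom_ref.
* **autosomal recessive** — affected twin hom_alt, both parents het, and
  neither the co-twin nor any sibling hom_alt.
* **autosomal dominant** — affected twin het, all others hom_ref; with
  incomplete penetrance enabled, exactly one het parent is tolerated and the
  candidate is annotated with a penetrance-exception note.
* **homozygous screen** — affected twin hom_alt, others unconstrained; a
  co-twin that is also hom_alt yields a `concordant_twin` note (such
  candidates are eliminated as causative downstream but are counted, matching
  how homozygous screens are reported).

No-call policy: under `permissive` (default) a `./.` genotype at a position
whose required class is hom_ref counts as compatible but attaches a
`no_call_supported` note, so weakly genotyped candidates survive to evidence
review instead of silently disappearing — this reproduces the observed
behaviour of joint-called family data, where a proband-only call with
no-calls elsewhere is a classic false-positive signature that should be
*flagged*, not hidden.  Under `strict`, any required member with a no-call
excludes the variant; the strict candidate set is provably a subset of the
permissive one.  The proband's own genotype must always be an actual call of
the required class.

Twin concordance counts a variant as present in a twin iff that twin carries
at least one alt allele; sites present in neither twin do not enter the
percentage.

## Evidence review

Per-sample pileup summaries (depth, alt reads, per-strand splits; a TSV
schema, 1-based) are reduced to flags:

| flag | rule | default |
|---|---|---|
| low_depth | depth < min_depth | 20× |
| low_alt_support | carrier with alt reads < 3 or AAF < 0.20 | — |
| strand_bias | ≥ 3 alt reads all on one strand, or two-sided Fisher exact p < 0.05 on [(ref_fwd, ref_rev), (alt_fwd, alt_rev)] | — |
| aaf_genotype_conflict | het AAF ∉ [0.25, 0.75]; hom_alt AAF < 0.90; hom_ref AAF > 0.05 | — |

Verdict per sample: `likely_artifact` iff a called carrier shows low alt
support or strand bias; `uncertain` iff only depth or an AAF conflict (or a
no-call genotype) undermines the call; else `supported`.  The cohort verdict
is the worst verdict among alt-carrying samples.  The numeric thresholds are
*conventions*, not published rules: they are chosen so that the canonical
qualitative judgements reproduce (a strand-imbalanced het at 9% AAF and a
1-of-19-read homozygote flag as likely artifacts; a low-depth but balanced
het stays uncertain), and every threshold is configurable.  Note that a
Fisher test at p < 0.05 flags a few percent of genuinely unbiased carriers
by construction; the flags are advisory inputs to review, not a classifier
with guaranteed specificity.

## VCF handling

Reading goes through pysam (which distinguishes FILTER `.` from `PASS`).
Multiallelic records are decomposed on the fly: against alt *k*, sample
alleles equal to *k* map to 1, reference to 0, and any *other* alt allele to
missing.  A `1/2` genotype therefore becomes a half-call for each decomposed
alt and classifies as no_call — deliberately conservative: it can never be
mistaken for hom_ref (which would fabricate de novo support) nor claimed as
a clean het for either alt.  Annotations are site-level; per-alt (Number=A)
annotation splitting is out of scope, as inputs are expected pre-decomposed
by the annotator.

## Synthetic cohorts

The generator emulates the statistical structure the screens assume, not
sequencing physics:

* unlinked biallelic sites; site frequencies from Beta(0.5, 5) truncated to
  [10⁻⁴, 0.5] (rare-skewed spectrum); founders binomial in the site
  frequency; offspring by Mendelian allele transmission; twins
  genotype-identical at all background sites;
* planted sites with genotypes set deterministically (not sampled) to their
  model's admitting pattern, so truth tables are exact; pathogenicity scores
  drawn to meet a per-variant tier target (strict_pass: CADD ~ U(21, 35),
  REVEL ~ U(0.5, 0.99), one damaging tool; liberal_only: one damaging tool
  but a failing quantitative threshold; fail: no damaging tool);
* artifacts realized in the pileup summary (and, for `no_call_others`, in the
  VCF itself): the `low_aaf_carrier` kind writes a het genotype in the VCF but
  ~9% alternate fraction in the pileup — the signature of a miscalled site;
* per-sample read depth around 160× (Poisson), matching high-coverage
  clinical exomes; QC metrics drawn near the published cohort's ranges;
* planted de novo and dominant sites are genuine transmission violations
  (both parents 0/0); the generator returns their keys as the exempt set for
  the Mendelian self-check, which must report zero violations elsewhere.

Default problem sizes (1000 background sites, two planted variants per
model) keep a full simulate-and-analyse cycle around a second while leaving
every stage's behaviour observable; the property suites run ten such cohorts
across seeds.  What passing tests on synthetic data do **not** show:
robustness to linkage, batch effects, indel-alignment artifacts, annotation
disagreement between transcript sets, or miscalled multiallelics — real
exomes fail in ways this generator does not model.

Reproducibility: one global seed, split into independent child streams
(sites, genotypes, annotations, pileup, QC) via `numpy` seed sequences; the
same configuration and seed yield byte-identical output files.

## Numerical and degenerate-input conventions

* Reported percentages round half-up to one decimal; cohort coverage means
  to 3 decimals, percentage columns to 2 (these conventions make the bundled
  QC table aggregate exactly to its published cohort averages).
* Allele fraction is undefined (absent) at zero depth; an empty QC table or a
  zero-total class breakdown is a hard error, an empty cohort is a valid
  all-zero report.
* Candidate tables are ordered by natural chromosome order (1..22, X, Y, MT),
  then position, then alt; reports are JSON-first with TSV mirrors, and two
  runs on identical inputs produce identical bundles.
* Pedigree invariants (exactly one affected member, who must be one of the
  twins; twins share both parents; parent references resolve) are enforced at
  construction with error messages naming the violated rule.

## Bundled data

`twinvar.datasets` ships the index family's published candidate tables
(5 de novo, 4 recessive, 6 dominant rows) and per-sample QC metrics.
Genomic coordinates are published for three candidates only (STOX1, HOXD8,
C1QTNF9); other rows carry deterministic placeholder positions and
cDNA-derived ref/alt alleles, sufficient for score-level analyses.  The
shipped 126-gene example panel reproduces the study panel's category sizes
(19 KFS / 24 CS / 83 other CSD) with a core of well-known spinal-deformity
genes padded by clearly labelled synthetic placeholder symbols — it
exercises the panel screen and is not a curated clinical resource.

## Known limitations

* SNV/indel, autosomal, biallelic analysis only: no CNVs or structural
  variants, no X-linked or compound-heterozygote models, no zygosity or
  kinship inference (monozygosity is taken as input).
* Review flags consume pileup summaries; the package does not realign or
  model base quality, and pileup extraction from BAM is left to external
  tooling.
* Absolute cohort-scale funnel counts from real exomes are not a contract:
  they depend on capture design, caller and annotator versions, and on the
  exact stage at which counts are taken.
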