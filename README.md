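# snptrait

Single-locus candidate-SNP association analysis for pediatric cohorts.

`snptrait` implements, as a tested and reusable pipeline, the analysis a
candidate-gene childhood-obesity study performs on a genotyped school
cohort: anthropometric standardization, allele/genotype frequency and
Hardy–Weinberg testing, case-control association, genotype-stratified
phenotype contrasts, and the Falconer additive/dominance effect
decomposition with dominance-type classification and effect-size grading.
It is aimed at researchers analysing per-child phenotype tables (sex, age,
anthropometry, bioimpedance, fasting biochemistry) joined with genotype
calls at a handful of named biallelic SNPs.

## The statistics at its core

**Standardization.** BMI-for-age is standardized with the LMS (Box–Cox)
method against a pluggable sex/age-indexed growth reference:

    z = ((X/M)^L − 1) / (L·S),    z = ln(X/M)/S  as L → 0

Children are dichotomized into normal-weight controls versus
overweight/obese cases by age/sex BMI cutoffs (IOTF-style tables, also
pluggable). Insulin resistance is indexed by
HOMA-IR = insulin (µU/ml) × glucose (mg/dl) / 405.

**Association.** Per SNP, genotype counts are tested for Hardy–Weinberg
equilibrium with both the Pearson chi-square (df = 1) and the exact
conditional test (probabilities of heterozygote configurations given the
allele counts), and case/control allele (2×2) or genotype (2×3)
distributions are compared by Pearson chi-square without continuity
correction. Phenotype means per genotype are contrasted against the
wild-type homozygote with Welch 95% intervals and rank-based
(Dunn–Bonferroni) p-values.

**Effect decomposition.** With genotype phenotype means and allele
frequencies p (major) and q (minor), the classical single-locus
decomposition is

    m = (mean_AA + mean_aa)/2,   a = mean_aa − m,   d = mean_Aa − m,
    α = a + d(p − q),            α₁ = p·α

where a is the additive effect (oriented toward the minor allele), d the
dominance deviation, α the average effect of an allele substitution and
α₁ the minor allele's average effect. Dominance is typed by |d/a|
(none / partial / complete / overdominance) and the minor allele's effect
on zBMI is graded very weak (<0.05), weak (<0.2), medium (<0.8) or strong,
with direction from its sign.

A seeded synthetic-cohort generator (`snptrait.simulate`) draws genotypes
under Hardy–Weinberg proportions and phenotypes from the same single-locus
model, so every stage of the pipeline is verifiable without any external
data.

## Worked example

```python
from snptrait import SnpStudy, make_paper_fixture

cohort, lms, iotf = make_paper_fixture(seed=1)   # n = 773, five SNPs
results = SnpStudy(cohort, lms_table=lms, iotf_table=iotf).fit()
print(results.summary())
```

prints

```
Single-locus SNP-trait association study
  samples: 773  (case 225 / control 548)
  SNPs: 5

  SNP          gene   n    q_minor  HWE p(exact)  allele p  genotype p
  rs1137101    LEPR   631  0.494    0.426         0.0148     0.000571
  rs9939609    FTO    517  0.474    0.251         0.258         0.479
  rs2229616    MC4R   433  0.010    1             0.803         0.802
  rs17782313   MC4R   360  0.208    1             0.299       0.00828
  rs1801282    PPARG  274  0.099    0.49          0.319         0.351

  Effect decomposition (zBMI):
  SNP          a        d        midpoint alpha1   dominance        grade
  rs1137101    -0.190   +0.344     0.507  -0.094   overdominance    weak decrease
  rs9939609    +0.135   -0.061     0.729  +0.070   partial_dominance weak increase
  rs2229616    not computable (empty genotype class)
  rs17782313   +0.452   -0.565     1.073  +0.097   overdominance    weak increase
  rs1801282    -0.451   +0.470     0.300  -0.067   complete_dominance weak decrease  [minor n<5]
```

Reading the output: per SNP the analysis n is the number of genotyped
children (not the cohort size — call rates differ by SNP), `q_minor` the
minor-allele frequency, and the three p-values test Hardy–Weinberg
equilibrium and case/control allele- and genotype-distribution
differences. The effect block gives the additive effect `a`, the dominance
deviation `d`, the homozygote midpoint, and the minor allele's average
effect `alpha1`, whose magnitude drives the grade. The rare MC4R coding
variant has no minor homozygotes at this sample size, so its decomposition
is reported as not computable; the PPARG row is flagged because it rests
on fewer than five minor homozygotes. `results.save(outdir)` writes every
table as TSV plus a full-precision JSON report.

The same analysis is scriptable from the shell:

```sh
snptrait simulate --outdir fixture --seed 1
snptrait associate --phenotypes fixture/phenotypes.csv --genotypes fixture/genotypes.csv \
    --lms fixture/lms_reference.csv --iotf fixture/iotf_cutoffs.csv --outdir out
snptrait reproduce --outdir repro
```

## Layout

- `snptrait.io` — domain types, phenotype/genotype/reference-table readers
  and writers (CSV/TSV and a biallelic-SNP VCF subset), cohort joining
- `snptrait.anthro` — BMI, LMS z-scores, IOTF classification, HOMA-IR,
  stratified descriptives with Dunn–Bonferroni comparisons
- `snptrait.assoc` — genotype counting, Hardy–Weinberg (chi-square and
  exact), case-control tests, genotype-stratified contrasts
- `snptrait.falconer` — the effect decomposition, dominance typing,
  effect grading
- `snptrait.simulate` — the seeded synthetic-cohort generator
- `snptrait.model` — `SnpStudy` / `SnpStudyResults` facade
- `snptrait.pipeline`, `snptrait.cli` — orchestration and the `snptrait`
  command

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
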