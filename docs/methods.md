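# Methods

This note records the statistical procedures `snptrait` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Cohort model and derived phenotypes

A cohort is one row per child: sex, exact age in days (given directly or
as an exam-minus-birth calendar-day difference), weight, height, optional
circumferences, bioimpedance and fasting biochemistry, plus one genotype
call per panel SNP. Genotype calls are unordered allele pairs; "A/G" and
"G/A" are the same call, and every counting routine is invariant under
permuting allele symbols. Missing cells are encoded with an explicit `NA`
sentinel in all file formats, never 0 or an empty string, because several
biochemistry analytes are legitimately near zero. Per-SNP analysis n is
always the number of non-missing calls, never the cohort size.

BMI is weight/(height in m)²; heights below 50 are rejected as probable
meters rather than silently converted. BMI-for-age z-scores use the LMS
method, z = ((X/M)^L − 1)/(L·S), switching to the exact L→0 limit
ln(X/M)/S when |L| ≤ 1e−8; L, M and S are interpolated linearly in age,
each parameter independently, from a pluggable sex/age-indexed reference
table. Ages are accepted up to one grid step beyond the table and held
constant there; beyond that the lookup errors with the covered range.
Growth-reference and BMI-cutoff tables are inputs, not embedded
constants: which national/international reference a given analysis should
use is a user decision. Weight category is dichotomous — overweight and
obese are merged into the case group — and a BMI exactly at the
overweight cutoff classifies as a case (deterministic ≥ convention).
HOMA-IR is insulin × glucose / 405 in the stated units.

## Stratified comparisons

Descriptive tables stratify by sex or weight category and compare strata
pairwise. The default test is rank-based: Dunn's z on mean ranks with the
tie-corrected null variance N(N+1)/12 − Σ(t³−t)/(12(N−1)), with raw
p-values multiplied by the number of stratum pairs (Bonferroni) and
capped at 1. A Welch t alternative is selectable per run. The rank-based
default was chosen because heavy-tailed biochemistry (insulin, leptin,
ferritin) makes mean-rank comparisons the safer default for this data
class; both routes share the same adjustment. A comparison in which
either stratum has fewer than two non-missing values is reported as
not-computable rather than raising.

## Single-locus association

Major/minor allele orientation comes from the declared panel; for
undeclared SNPs the major allele is the more frequent one over all
non-missing calls, ties broken lexicographically. Hardy–Weinberg
equilibrium is tested two ways and both are always reported: the Pearson
chi-square of observed versus (p², 2pq, q²)·n with df = 1 and no
continuity correction, and the exact conditional test — given the allele
counts, heterozygote counts share the parity of the minor-allele count,
and the p-value is the total probability of configurations no more
probable than the observed one. The exact test is the headline value.
It is computed with a probability recurrence over heterozygote counts
anchored near the conditional mode, so totals of a few hundred are exact
and overflow-free; the test suite checks it against an independent
log-factorial enumeration for totals up to 200. Monomorphic samples
return p = 1.

Case-control tests are Pearson chi-squares on the 2×2 allele or 2×3
genotype table, no continuity correction. Genotype columns with zero
total (rare variants with no minor homozygotes) are dropped with df
reduced; a table degenerate to one column yields a flagged
not-computable result instead of an exception. Genotype-stratified
phenotype tables report n/mean/sd per genotype × stratum with compact
letter displays from the Dunn pairwise tests (Bonferroni within the
genotype family; classes with fewer than two observations are printed
but excluded from comparisons). Contrasts against the wild-type
homozygote carry Welch 95% intervals and rank-based p-values adjusted
within the per-SNP family. No genome-wide correction is applied — the
intended use is a handful of candidate SNPs, mirrored in the per-table
Bonferroni families.

## Effect decomposition

From genotype means and allele frequencies (p major, q minor):
m = (mean_majhomo + mean_minhomo)/2, a = mean_minhomo − m,
d = mean_het − m, α = a + d(p − q) with the substitution oriented toward
the minor allele, α₁ = p·α. The reported `population_mean` is the
homozygote midpoint m; the Hardy–Weinberg frequency-weighted mean
M = m + a(q − p) + 2pqd is computed and reported under
`freq_weighted_mean`. The `aecme` field ("average effect of changing to
the minor allele") reports α: no variant of the substitution-effect
formula reproduced the corresponding published row from its printed
inputs, so the package reports the standard quantity under that heading
and its reproduction report flags the difference rather than guessing an
undocumented formula.

Dominance is typed by r = |d/a| with a relative band of 0.25:
r ≤ 0.25 none, |r − 1| ≤ 0.25 complete, below partial, above
overdominance; a = 0 with d ≠ 0 is overdominance, a = d = 0 degenerates
to no dominance. The band width is a package decision — the grading has
no published numeric rule — chosen as the loosest symmetric band that
still separates the four qualitative outcomes cleanly; it is
configurable. Effect grades compare |x| against 0.05 / 0.2 / 0.8 with
boundaries assigned upward (the published inequalities are strict on
both sides and leave boundaries undefined); the graded x defaults to α₁
and is configurable. The decomposition is exactly invertible
(`genotype_means()` reconstructs the three inputs), equivariant under
phenotype negation, and maps (a, α, p, q) → (−a, −α, q, p) under
major/minor relabeling; these invariants are property-tested.

Pipeline mode computes genotype means from individual records; table
reproduction mode pools published per-stratum (n, mean) pairs with exact
n-weighted means. Both share the same decomposition routine. SNPs with an
empty genotype class yield a not-computable entry carrying whatever
remains defined; minor-homozygote classes under five observations are
flagged as fragile.

## Reproduction of the published tables

The packaged JSON reference stores the published genotype counts per
group, the published case/control allele counts, the per-genotype
stratum means of BMI and zBMI, and the published effect table (values as
strings, preserving printed precision). Every recomputed cell is compared
at the printed precision, accepting either rounding or truncation of the
last digit since the published tables use both conventions. Known
discrepancies, all flagged by the report rather than reconciled: the
published BMI effect rows are not reproducible by pooling the published
BMI stratum means; one published allele-count row is inconsistent with
its own genotype row; one published minor-allele average effect differs
from the value its printed inputs imply; and the entire PPARG-2 effect
column — resting on two minor homozygotes, as the published table itself
cautions — reproduces in none of its cells and is excluded from any
numeric acceptance check.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not a physiological model. Genotypes are multinomial under (p², 2pq, q²)
per SNP, independent across children and loci (the study design analyses
each SNP marginally; no linkage or epistasis is simulated). The
standardized adiposity phenotype is baseline + per-locus genotype shift
(−a, +d, +a) + Gaussian noise; BMI is obtained by inverting the LMS map
through a toy growth reference (Box–Cox power −1.5, median rising gently
with age, slightly different by sex), weight from BMI and a sex-specific
height distribution. The toy BMI-cutoff table is constructed to put a
target fraction of the cohort — 30.1% by default, the study's case rate —
above the overweight cutoff, using the analytic mean and variance of the
simulated zBMI marginal. Ancillary anthropometry and biochemistry follow
documented linear-plus-noise recipes around the adiposity signal with
first moments loosely matched to a school-age population; they exist so
downstream table code always has inputs and claim no physiological
realism (no measurement-error model, no full covariance structure).

Study-scale defaults: n = 773 with 381 boys, five SNPs at minor-allele
frequencies 0.47 / 0.46 / 0.01 / 0.21 / 0.09 with per-SNP call rates
617/530/437/352/272 out of 773, and planted zBMI effects equal to the
published per-SNP point estimates (the PPARG-like locus uses a modest
(−0.15, 0.10) because its published pair is the flagged-irreproducible
one; the rare MC4R coding variant carries no planted effect and its
maf of 0.01 deliberately produces zero minor homozygotes in most runs,
exercising the degenerate-class code paths). All randomness flows from
one integer seed; equal parameters and seed reproduce the files byte for
byte.

Passing tests on this generator demonstrate internal consistency —
calibration, planted-effect recovery, invariances — under idealized
Gaussian, independent-locus conditions; they do not certify behavior on
real cohorts with genotyping error, informative missingness or secular
trends.

## Numerical choices and problem sizes

Exact-HWE enumeration is O(minor allele count) per test with ratio
recurrences; the chi-square variant handles monomorphic input as
chi² = 0, p = 1. The cohort writer emits 12 significant digits so
write/read round-trips preserve values to that precision and missingness
exactly. Simulation-based tests use fixed seeds and sizes chosen for
sub-minute runtimes: 1000 null replicates at n = 300/300 for type-I
calibration (asserted within 5% ± 1.5%), 500 replicates for contrast-CI
coverage (≥ 93%), 200 replicates for power checks (≥ 80% at planted
shifts whose analytic rank-test power is ≈ 0.9), n = 10⁴ for
planted-effect recovery (within 3 standard errors), n = 10⁵ for genotype
frequency convergence. The acceptance script reruns the printed-input
reproductions and these simulation checks end-to-end in a few seconds.

## Known limitations

No logistic-regression odds ratios, covariate adjustment, haplotype or
multi-locus modelling, imputation, pedigree structure, or heritability
estimation — all outside the intended scope. VCF support is read-only
and restricted to biallelic SNP records with GT. The compact letter
display enumerates cliques and is intended for the three-genotype case,
not for large numbers of groups.
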