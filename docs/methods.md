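# Methods

## Study design being modelled

The package operationalizes a cross-sectional gene–diet interaction
analysis in school-aged children: ~1100 participants around age 11,
genotyped on a targeted array, with a 16-item food frequency questionnaire
(FFQ), measured anthropometry converted to age- and sex-specific BMI
z-scores (BMIz), and lifestyle covariates (leisure-time physical activity,
sleep duration) plus two ancestry principal coordinates. The genetic
exposure is a 30-SNP BMI risk-allele panel of well-replicated common
variants.

## Risk scores

Dosage d_ij counts risk alleles (0/1/2) of individual *i* at SNP *j*;
missing genotypes are allowed. Four schemes are computed:

* **unweighted** — Σ_j d_ij over non-missing SNPs. An integer count when
  nothing is missing; with missingness it is a sum over fewer SNPs, which
  matches the convention of counting observed risk alleles.
* **weighted (speliotes / finhit / ratio)** — Σ_j w_j d_ij / n_nonmissing,i,
  i.e. an *average score per non-missing SNP*. This follows the PLINK
  `--score` behaviour of averaging over non-missing entries so individuals
  with different missingness remain comparable. A `per_allele=True` flag
  divides by 2·n_nonmissing instead for strict per-allele PLINK
  compatibility.

Individuals with every panel SNP missing cannot be scored and are dropped
with a warning. Dichotomization splits the unweighted count at the cohort
median, assigning the median value itself to the **low** group (so a median
of 27 yields low ≤ 27, high ≥ 28).

The packaged panel file carries the real 30 rsIDs and nearest-gene labels;
its risk/other alleles, effect sizes and the default risk-allele
frequencies are *synthetic, plausible stand-ins* (the original per-allele
weights are not redistributed), and the file name says so. The `finhit`
weight column defaults to the `speliotes` column, making the ratio scheme
degenerate (all weights 1) until a user supplies cohort-specific weights;
this is deliberate and documented rather than inventing a second weight
set. The ratio scheme's scale is therefore relative, not in BMI units.

## Dietary exposures

FFQ ratings 1–7 are recoded to weekly frequencies with the mapping
1→0, 2→0.5, 3→1, 4→2.5, 5→5.5, 6→7, 7→14 times/week. Only the endpoints
(1 = never = 0, 7 = several times a day = 14) are contractual; the interior
values are a documented convention and fully overridable, with validation
that any user mapping is monotone and correctly anchored. Two summary
indices are sums of weekly frequencies: the sweet treat index (sweet
pastry, biscuits/cookies, ice cream, sugary juice drink, sugary soft
drink, sweets/chocolate) and the plant consumption index (cooked
vegetables, fresh/grated vegetables, fruit/berries). Compositions are
configurable. A missing component makes the index missing (no partial
sums).

## BMI z-scores

The LMS method: z = ((BMI/M)^L − 1)/(L·S) for L ≠ 0 and z = ln(BMI/M)/S for
L = 0, with (L, M, S) linearly interpolated in age separately within sex
(a simple, monotone convention; spline interpolation of published LMS
tables changes z-scores only in the third decimal at half-year knots). The
reference table is pluggable; the package ships a *synthetic* reference
with plausible pediatric curves for testing, and users should supply a
published IOTF/WHO coefficient file for substantive work. The exact inverse
transform is provided and round-trips to 1e-10.

## Interaction regression

`fit_interaction` fits OLS on
`outcome ~ 1 + g + e + g·e + covariates` with complete-case handling,
two-sided p-values from the t distribution with residual df, and 95% CIs
b ± t₀.₉₇₅,df·SE. Standardized coefficients (Beta) are b·SD(x)/SD(y)
computed on the analysis sample; for the interaction term the *product
variable itself* is standardized — the convention is stated because
alternatives (standardizing components before multiplying) exist. The
design matrix is checked for constant columns and rank deficiency (via
pivoted QR) so errors name the offending term. At least 10 complete cases
beyond the parameter count are required.

Scores enter the model uncentered, as they would in standard statistical
software; this inflates the variance of the product term's estimate
relative to a centered parameterization but leaves the interaction test
identical.

## Screening cascade

* Level 1 (whole score): each food × scheme interaction is tested with
  covariates sex, physical activity, sleep, PC1, PC2. Interaction is
  claimed at p < 0.15. Borderline results (default band 0.15 ≤ p < 0.25,
  configurable) are refitted with the scheme's score dichotomized at its
  median, and both p-values are reported. A food is flagged when any
  scheme's continuous or dichotomized p-value is below 0.15.
* Level 2 (per SNP): for a flagged food, each SNP's dosage replaces the
  score in the same model. SNPs are selected when the interaction
  coefficient has the *same sign* as the whole-score interaction for that
  food and p < 0.2. "Same direction" is interpreted against the whole-score
  interaction sign because that is the quantity that flagged the food; the
  referent is stored explicitly in `FoodSpecificGRS.reference_direction`
  and can be overridden. In the pipeline the reference sign is taken from
  the scheme with the smallest continuous p-value for that food.

The liberal thresholds reflect the low power of interaction tests relative
to main effects: the type-I error rate is deliberately raised at the
screening stage, and no multiple-testing correction is applied by default
(a Benjamini–Hochberg helper is available for reporting). Under a global
null the expected per-SNP inclusion rate is p<0.2 (two-sided) ∩ direction
match ≈ 10%, which the calibration suite verifies.

* Validation: the food-specific score (unweighted count over the selected
  subset) is refitted under model 1 (sex) and model 2 (sex + physical
  activity + sleep). Ancestry PCs are used in the screening fits but not in
  the validation models, mirroring the two covariate sets of the original
  design.
* Stratified effects: the food term is estimated separately below/above
  the median of the food-specific score (model-2 covariates), alongside a
  joint group × food interaction model. With no covariates the joint model
  reproduces the stratum slopes exactly (dummy-interaction algebra), which
  is used as a correctness check.
* Shared SNPs: exact set algebra over the per-food selections — union,
  full intersection, membership matrix and exclusive Venn-region counts
  keyed by alphabetically sorted food combinations.

Every model is complete-case; per-model sample sizes are recorded in the
pipeline's structured log.

## Synthetic data generator

The generator emulates the assumed data-generating process, not any real
family of children:

* **Genotypes** — independent per SNP, Binomial(2, freq) (Hardy–Weinberg),
  no linkage disequilibrium (the panel's loci are on separate regions and
  nothing downstream uses LD). Entries are masked missing completely at
  random, default rate 0.001 (genotyping rate ~99.9%). Default risk-allele
  frequencies are chosen so the expected risk-allele count is ≈27.6,
  putting the cohort median near 27.
* **Covariates** — sex ~ Bernoulli(0.5); age ~ N(11.3, 0.2) years;
  physical activity ~ N(6.7, 2.7) h/week truncated at 0; sleep
  ~ N(9.8, 0.7) h/night; PC1, PC2 ~ N(0, 1).
* **FFQ** — per item, ratings are 1 + Binomial(6, q) with q calibrated by
  root finding so the recoded weekly mean matches a target (defaults range
  from pizza ≈ 0.55 to milk ≈ 10.5 times/week). Only means are calibrated;
  real rating distributions may be more dispersed or zero-inflated. FFQ
  missingness is supported via a parameter (default 0).
* **BMIz** — the linear model
  Σ m_j d_ij + Σ a_f x_if + Σ γ_jf d_ij x_if + Σ λ_c z_ic + ε,
  ε ~ N(0, noise_sd); missing dosages/frequencies contribute 0.
* **Seeding** — a master seed spawns independent sub-streams (genotypes,
  covariates+FFQ, noise), so identical configuration and seed give
  byte-identical outputs.

The demo ground truth (`demo_effect_spec`) plants per-SNP main effects of
0.055 BMIz per allele (the 30-SNP score then explains ~3.7% of BMIz
variance and the low/high group difference is ≈0.26 BMIz) and the four
validated interactions on the published per-food SNP subsets with the
reported fully adjusted coefficients (pizza 0.082, sweets/chocolate 0.033,
sugary juice drink 0.012, hamburger/hotdog 0.052 per risk-allele ×
times/week), with food main effects equal to the reported negative
coefficients at zero alleles. What passing tests on these data show is
that the *pipeline* recovers what it assumes; they cannot show robustness
to LD, genotyping error, FFQ misreporting correlated with BMI, population
stratification beyond two Gaussian PCs, or non-linear dietary effects —
none of which the generator produces.

## Calibration experiments (`foodgrs.calibration`)

* Type-I error of the interaction test: 1000 null replicates at n = 1000;
  the rejection rate at α = 0.05 should be 5% ± sampling noise.
* Null cascade inclusion: 200 replicates × 30 SNPs; expected ≈ 10%.
* CI coverage: 200 replicates at n = 1142 with γ = 0.08 planted on the
  five shared core loci; the validation model-2 interaction CI should
  cover γ ≈ 95% of the time.
* Stratified sign recovery: 200 replicates at n = 1142 with stratum-level
  slopes −0.13/+0.15 and unit noise (BMIz SD 1.0); both signs should be
  recovered in ≥ 95% of replicates given the implied ~2.2–2.6 SD effect
  sizes.

Replicate counts and cohort sizes were chosen to keep each experiment in
the tens of seconds while leaving binomial Monte-Carlo error well inside
the asserted bands.

## Numerical and design choices

* Chi-square group comparisons default to Pearson's statistic without
  continuity correction (the headline statistic of mainstream GUI
  software); a flag enables Yates correction. t-tests default to pooled
  variance with a Welch option.
* VCF input is parsed with cyvcf2 (GT fields only); flipped REF/ALT
  orientation relative to the panel is re-oriented, non-matching alleles
  raise an error naming the rsIDs, strand-ambiguous panel entries (A/T,
  C/G) warn, and multi-allelic records are rejected. VCF export is a
  minimal deterministic GT-only serializer (no date header) so outputs are
  byte-reproducible.
* Ties at the median go to the low-risk group; a constant score vector
  dichotomizes to all-low with a warning.
* The pipeline's structured log is timestamp-free JSON to preserve
  byte-level determinism; human-readable logging goes to stderr.
* `alpha_snp = 0` is allowed as a degenerate setting: the cascade selects
  nothing and the pipeline ends cleanly after screening.

## Known limitations

* No LD, imputation, proxy-SNP search, or genotyping-error model.
* Eating-habit clusters are accepted only as an input categorical
  covariate; deriving them (factor analysis + hierarchical K-means) is out
  of scope, and categorical exposures are not screened as foods.
* The shipped LMS reference and panel weights are synthetic stand-ins;
  substantive analyses must supply published files.
* OLS with homoscedastic errors only — no robust/clustered SEs or mixed
  models.
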