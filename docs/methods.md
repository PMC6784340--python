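# Methods

This note records the statistical model the package implements, what the
synthetic-cohort generator does and does not emulate, and every numerical
convention a maintainer might want to question.

## The scientific setting

The analysis concerns patients with acute coronary syndromes who underwent
coronary angiography and have at least one major epicardial vessel with
≥50% stenosis. Severity is the number of diseased major vessels (1, 2 or
3; left-main stenosis counts as three-vessel), and the primary outcome is
the binary contrast multi-vessel (≥2) versus single-vessel disease. The
exposure is a weighted genetic risk score (GRS) built from common variants
that predispose to type 2 diabetes (T2D) in East Asian populations. The
question is whether genetic predisposition to T2D raises the odds of
severe disease, and how much of that association runs through diabetes
itself.

## Genetic risk score

For subject *i* with effect-allele dosages `g_ij ∈ [0, 2]` over a panel of
`n` QC-passed SNPs with published per-allele log-odds `β_j > 0`:

* weighted score `w_i = Σ_j β_j g_ij`;
* rescaled score `s_i = w_i · n / Σ_j β_j`, so one score point corresponds
  to roughly one risk allele and, when all weights are equal, the rescaled
  score *is* the risk-allele count (this identity is made exact in code by
  bypassing the multiply-divide in the constant-weight case);
* unweighted score `u_i = Σ_j g_ij` for sensitivity analyses.

Weights files with negative published betas are normalised at load time
(swap effect/other allele, negate beta, reflect the EAF), so stored
weights always refer to risk alleles. Missing dosages are imputed as
`2 × EAF` from the panel frequency; subjects missing more than 10% of
panel SNPs are dropped with a warning. Tertiles are rank-based with ties
broken by stable input order and remainder subjects allocated to the
lower-score groups, so 1414 subjects split 472/471/471.

Allele alignment against a VCF resolves four presentation frames (direct
or swapped allele order, original or complemented strand). Palindromic
A/T and C/G SNPs are intrinsically strand-ambiguous and resolve only in
the two non-flipped frames; anything unresolvable raises an error naming
the SNP rather than guessing.

## Variant QC

The exact Hardy-Weinberg test conditions on the observed allele counts,
enumerates every heterozygote count of the correct parity via the standard
stable recurrence, and sums the probabilities of all configurations no
more probable than the observed one (plain two-sided convention, ties
included; not mid-p). The test is checked in the suite against exhaustive
enumeration in exact rational arithmetic for every genotype triple with
n ≤ 30.

Two HWE screens are applied: a permissive floor at p < 1e-5 (genotyping-
error scale) and a panel-wise Bonferroni screen at `0.05 / n_snps`
(0.05/42 ≈ 0.00119, reported as 0.001). Further filters: monomorphic
after rounding (minor-dosage-sum zero), missing call rate ≥ 5%, and
imputation info score < 0.7 (strict, so 0.70 survives). HWE is computed
on hard calls obtained by rounding dosages when every call is within 0.1
of an integer; materially fractional (imputed) dosages skip the HWE
screens with a logged note, since the appropriate dosage-based test is a
different statistic. Filtering is idempotent.

## Association models

All fits are maximum-likelihood logistic (or multinomial-logistic)
regressions through statsmodels, with Wald p-values and symmetric
log-scale 95% CIs (`exp(β ± 1.96·se)`). The adjustment tiers are:
model 1 — age, sex, BMI; model 2 — + current smoking, hypertension,
hypercholesterolemia; model 3 — + T2D status. Exposure codings: per
rescaled point; per sample SD of the score; tertile contrasts against the
low tertile with a separate 0/1/2 ordinal trend term; or T2D status
itself (for which model 3 is meaningless and skipped). Separation is
flagged when any |β| exceeds 15; convergence is the optimiser's criterion
with a 100-iteration cap.

The vessel-count model is a multinomial logit with one-vessel disease as
reference, reported per SD of the score for the 2-vs-1 and 3-vs-1
contrasts at each adjustment tier.

The dose-response uses a restricted cubic spline (truncated-power basis
normalised by the squared boundary span, linear beyond the boundary
knots), default 4 knots at the 5/35/65/95% score quantiles (3 and 5 knots
available at their conventional quantiles). Nonlinearity is the
likelihood-ratio test of the k−2 nonlinear terms against the linear
model — the one place an LRT replaces a Wald test. The odds-ratio curve
is referenced to the cohort median, where OR = 1 by construction.

Subgroup analyses fit the score (per SD, scaled by the full-sample SD so
strata are comparable) within each stratum, adjusted for age and sex
except that the stratifying covariate itself is dropped when it is age or
sex; the interaction p is the Wald test of the score × factor product
term in the pooled model. Strata with a single outcome level are reported
and skipped. The per-SNP scan fits each SNP additively with age and sex,
without multiplicity adjustment (it feeds a per-SNP display).

Baseline descriptives report median (IQR) with Mann-Whitney U for
continuous variables (a t test for variables flagged normal) and n (%)
with Pearson chi-square for categorical ones; the Yates correction is off
by default and switchable.

## Mediation triangle

With `β_G` the per-point effect of the score on T2D (age-, sex- and
BMI-adjusted), `β_D` the fully adjusted effect of T2D on multi-vessel
disease, and `β_O` the fully adjusted per-point effect of the score on
multi-vessel disease, the expected effect under pure mediation is taken
as `β_E = β_G × β_D` with first-order delta-method SE
`√(β_G² se_D² + β_D² se_G²)` (a parametric-bootstrap SE is available and
agrees within 3%). The comparison statistic is
`z = (β_O − β_E)/√(se_O² + se_E²)` referred to the standard normal — the
large-sample form of a t comparison; at n ≈ 1400 the df refinement moves
p by under 0.001. Two approximations are deliberate and documented: the
β_O/β_E sampling covariance is ignored (the two-sample style of the
test), and the product rule itself is a convention on the log-odds scale.

On that second point: odds ratios do not collapse over a binary mediator,
so a data-generating process in which the score acts *only* through T2D
yields a marginal score→severity log-odds of roughly
`β_D · ∂E[T2D]/∂score ≈ β_G β_D p̄(1−p̄)` — several-fold smaller than the
product `β_G β_D`. The triangle null `E[β_O] = β_G β_D` therefore holds
not in that structural pure-mediation regime but in data where the total
observed effect happens to sit on the product, which is exactly the
situation the default generator reproduces (and where the suite verifies
the comparison's p-values are uniform). The attenuation fraction
`1 − β_with-T2D / β_without-T2D` (per-SD coefficients, models 2 vs 3) is
reported alongside; under a generator with no direct effect the model-3
per-allele OR converges to 1, which the suite checks at n = 100 000.

## Multiple imputation

Chained equations over the covariates with missing values: continuous
variables by predictive-mean matching (ridge-stabilised linear predictor,
5 nearest observed donors, one drawn at random), binary variables by a
logistic fit and Bernoulli draw; 10 cycles, m = 9 completed tables by
default, all other numeric baseline variables plus outcome and score as
predictors. Outcomes and genotypes are never imputed — rows must be
complete in them. Pooling follows Rubin's rules: pooled estimate the
mean, total variance `W̄ + (1 + 1/m)B`, p from the normal reference. The
implementation is the package's own small chained-equations engine, which
gives per-variable method control and a bit-for-bit seed contract; its
calibration (5% type-I error after pooling over m = 9, convergence to the
complete-data fit as the missingness rate vanishes) is tested.

## Power

Each replicate draws n scores from N(0, σ²), assigns cases from a
logistic model with slope ln(OR) and intercept calibrated by bisection
(Gauss-Hermite quadrature for the normal expectation) to the target case
fraction, fits the univariable logistic with a dedicated two-parameter
Newton solver (equal to the general ML fit to 1e-8, asserted in a test),
and scores a two-sided Wald rejection at α. The closed-form approximation
`Φ(|β|σ√(n p(1−p)) − z₁₋α/₂)` is emitted alongside: the two bracket what
dedicated power calculators report, whose internal design assumptions
(cohort-style versus 1:1 case-control sampling) materially move the
answer — for the study design at OR 1.04 the closed form gives ≈0.80
under a 1:1 split and ≈0.76 under the observed 924:490 split. The package
simulates the observed split.

## Synthetic cohort generator

Defaults encode the study conditions: 1414 subjects, a 42-SNP panel with
EAFs uniform on (0.10, 0.90) and per-allele weights uniform on
(0.04, 0.25) (the published per-SNP values are not reproduced in the
available text, so ranges spanning typical East Asian T2D loci are used),
13 SNPs flagged pleiotropic, genotypes binomial(2, EAF) under HWE with
independent loci. HWE departures are injected by multiplying the
heterozygote probability by a configurable factor (default 3) and
renormalising.

Covariates match the study's marginals: age ~ N(60, (68−53)/1.349)
clipped to [30, 90]; BMI ~ N(24.7, (26.9−22.7)/1.349) clipped to
[15, 45]; male 78.6%, current smoking 41.6%, hypertension 53.3%,
hypercholesterolemia 18.0%, family history 8.3%; diagnosis UA/STEMI/
NSTEMI at 56.8/24.0/19.2%. T2D follows a logistic model with
per-rescaled-point coefficient ln(1.09) plus modest covariate effects
(age 0.03/yr, BMI 0.08/unit, male 0.10 — not identifiable from published
marginals, fixed once), intercept calibrated by bisection (tolerance 1e-4
on prevalence) to 20.4%. Multi-vessel disease follows a logistic model
with T2D coefficient ln(1.69), direct score coefficient ln(1.04) (chosen
to match the T2D-conditional score effect) and covariate effects,
calibrated to the 924/1414 case fraction; among multi-vessel subjects,
three- versus two-vessel status uses the same centred linear predictor
scaled by 1.5 (so the 3-vs-1 contrast exceeds the 2-vs-1 one), calibrated
to an even split. Missingness is MCAR by default on BMI, smoking and
hypercholesterolemia, with an age-dependent MAR switch; outcomes and
genotypes are never masked. One root seed expands into per-stage
substreams (panel / genotypes / phenotypes / missingness) so stages can
be regenerated independently and every output is bit-for-bit reproducible.

What the generator does **not** emulate — and what passing tests on it
therefore cannot show about real data: linkage disequilibrium between
loci (the panel's loci are modelled as independent, as selected), allele
frequencies and weights of the actual published panel, array-intensity
artefacts, genuinely informative (MNAR) missingness, and any covariate
correlation structure beyond what the outcome models induce.

## Simulation sizes and tolerances

Calibration and recovery properties are checked at sizes chosen to make
Monte-Carlo noise small relative to the assertion: effect recovery and
mediation-attenuation at one cohort of n = 100 000 (±10% relative on
coefficients; model-3 OR within 0.01 of 1 under pure mediation); CI
coverage over 500 cohorts of n = 1414 (band [0.93, 0.97]); spline and
interaction null calibration over 300 cohorts of n = 800–1000 (rejection
within three binomial SEs of 5%); triangle-comparison calibration over
120 cohorts of n = 700 (KS test) plus 1000 analytic null draws (type-I in
[0.035, 0.065]); power at 2000 replicates (MC SE ≈ 1 percentage point).
Exact identities (HWE versus enumeration, 2×2 closed forms, orientation
invariance, constant-weight identity) are tested to 1e-6 or tighter.

## Known limitations

Sample-level QC (call rate per subject, relatedness, sex checks,
ancestry) requires array data and is out of scope; the pipeline consumes
per-SNP info scores rather than performing imputation. The severity
model is hierarchical-binary (multi-vessel, then 3-vs-2), not
proportional-odds. The mediation machinery is the product-of-coefficients
triangle, not a formal two-sample Mendelian-randomization estimator, and
inherits the non-collapsibility caveat above. Angiographic vessel count
is a coarse severity measure compared with Gensini/Duke-type scores, and
the package does not attempt those.
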