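# grscad

Polygenic-score epidemiology for coronary severity: does genetic
predisposition to type 2 diabetes (T2D) raise the risk of *severe*
coronary artery disease (multi-vessel stenosis) in patients with acute
coronary syndromes, and is that association mediated by diabetes itself?

`grscad` is a tested, reusable implementation of the full analysis a
cardio-genetic-epidemiology group would run on such a case-control
angiography cohort:

* **Variant QC** — exact Hardy-Weinberg equilibrium test (conditional
  enumeration, two-sided sum-of-smaller-probabilities), missing-call-rate,
  imputation-info and monomorphism filters, with a panel-wise Bonferroni
  HWE screen at `0.05 / n_snps`.
* **Genetic risk score (GRS)** — effect-allele alignment against arbitrary
  VCFs (allele-order and strand-flip aware), weighted score
  `Σᵢ βᵢ gᵢ` from published per-allele log-odds, rescaled to risk-allele
  units by `n / Σᵢ βᵢ`, plus unweighted and pleiotropy-excluded variants
  and rank-based tertiles.
* **Association models** — baseline descriptives by severity group, nested
  logistic models (model 1: age, sex, BMI; model 2: + smoking,
  hypertension, hypercholesterolemia; model 3: + T2D) for per-allele,
  per-SD, tertile and T2D-status exposures; multinomial vessel-count
  model (1/2/3 vessels); restricted-cubic-spline dose-response with a
  likelihood-ratio nonlinearity test; subgroup and interaction analyses.
* **Mediation triangle** — the expected score→severity effect if it acts
  through diabetes, `β_E = β_G × β_D` (score→T2D times T2D→severity
  log-odds), with a delta-method SE, a z comparison against the observed
  effect `β_O`, and the attenuation fraction `1 − β_with/β_without` from
  adding T2D to the model.
* **Multiple imputation** — chained equations (predictive-mean matching
  for continuous, logistic draws for binary covariates) with Rubin's-rules
  pooling, `T = W̄ + (1 + 1/m)B`.
* **Power** — simulation-based power for the per-allele Wald test, with
  the closed-form approximation `Φ(|β|·σ·√(n·p(1−p)) − z₁₋α/₂)` alongside.
* **Synthetic cohorts** — a seeded generator producing genotypes under
  HWE (with optional injected departures), covariates matched to target
  marginals, and outcomes from calibrated logistic models, so every stage
  is testable without access to patient-level data.

## Worked example

A self-contained run simulates a cohort of 1414 patients with a 42-SNP
panel in which one SNP violates HWE, then runs QC, scoring and every
model:

```bash
grscad run-all --n 1414 --seed 11 --hwe-violation 7 --outdir run1
```

The QC stage drops the violating SNP (41 of 42 retained at the
`0.05/42 ≈ 0.001` threshold), the tertiles split 472/471/471, and
`run1/triangle.tsv` holds the mediation triangle:

```
                             edge       OR   ci_low  ci_high  p_compare  attenuation
       OR_G (GRS->T2D, per point) 1.071081 1.036637 1.106670   0.982627     0.121214
         OR_D (T2D->multi-vessel) 1.686395 1.227504 2.316839   0.982627     0.121214
OR_O (observed GRS->multi-vessel) 1.036995 1.007833 1.067002   0.982627     0.121214
OR_E (expected GRS->multi-vessel) 1.036537 1.008216 1.065654   0.982627     0.121214
```

Each score point (≈ one risk allele) raises T2D odds by ~7% in this
replicate; diabetics have ~1.69-fold odds of multi-vessel disease; the
observed per-allele severity OR (1.037) is statistically indistinguishable
from the product-expected one (1.037, p_compare = 0.98), and adding T2D to
the model attenuates the score's per-SD coefficient by ~12% — the pattern
of an association partially mediated by diabetes. `run1/table2.tsv`
carries the nested models (e.g. per-SD OR 1.15 → 1.16 → 1.14 across
models 1-3 here), `table3.tsv` the vessel-count contrasts, `forest.tsv`
the subgroups, and `power.tsv` the design's power.

Library use mirrors statsmodels: build a model object, `fit()`, read the
results:

```python
from grscad import SimConfig, generate_cohort, compute_weighted_grs
from grscad import GrsSeverityModel, MediationTriangle

cohort = generate_cohort(SimConfig(seed=11, hwe_violation_snps=(7,)))
grs = compute_weighted_grs(cohort.genotypes, cohort.panel)
res = GrsSeverityModel(cohort.phenotypes, grs).fit(exposure="per_sd")
print(res.summary())
tri = MediationTriangle(cohort.phenotypes, grs).fit()
print(tri.summary())
```

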