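"""Synthetic ACS-cohort generator.

Emulates the statistical structure the downstream analysis assumes: a panel
of independent T2D-risk SNPs under Hardy-Weinberg equilibrium (with optional
injected departures), per-subject risk-allele dosages, and phenotypes in
which type 2 diabetes depends on the rescaled genetic risk score and
covariates, and coronary severity (multi-vessel disease, then three- versus
two-vessel disease) depends on T2D, a direct GRS effect, and covariates.
Logistic intercepts are calibrated by bisection so that realized prevalences
hit their targets.

Default parameter values encode the study conditions being emulated:
n = 1414 ACS patients, 42-SNP panel, T2D prevalence 20.4%, multi-vessel
fraction 924/1414, per-score-point GRS->T2D odds ratio 1.09, T2D->multi-
vessel odds ratio 1.69, and a residual direct per-point GRS->severity odds
ratio of 1.04.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, VariantPanel
from .grs import compute_weighted_grs

__all__ = [
    "CovariateMarginals",
    "SimConfig",
    "SyntheticCohort",
    "generate_panel",
    "generate_genotypes",
    "generate_phenotypes",
    "inject_missingness",
    "generate_cohort",
    "calibrate_intercept",
]


@dataclass(frozen=True)
class CovariateMarginals:
    """Target marginal distributions for the baseline covariates.

    Continuous variables are summarised by median and IQR (the normal SD is
    recovered as IQR/1.349 and the draw clipped to a plausible range);
    binary variables by their prevalence.
    """

    age_median: float = 60.0
    age_iqr: tuple[float, float] = (53.0, 68.0)
    age_clip: tuple[float, float] = (30.0, 90.0)
    bmi_median: float = 24.7
    bmi_iqr: tuple[float, float] = (22.7, 26.9)
    bmi_clip: tuple[float, float] = (15.0, 45.0)
    male: float = 0.786
    current_smoker: float = 0.416
    hypertension: float = 0.533
    hypercholesterolemia: float = 0.180
    family_history_cad: float = 0.083
    prior_cvd: float = 0.25
    diagnosis_fracs: tuple[float, float, float] = (0.568, 0.240, 0.192)  # UA, STEMI, NSTEMI


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; `seed` fixes every output bit-for-bit."""

    n_subjects: int = 1414
    n_snps: int = 42
    eaf_range: tuple[float, float] = (0.10, 0.90)
    weight_range: tuple[float, float] = (0.04, 0.25)
    n_pleiotropic: int = 13
    beta_G: float = math.log(1.09)       # per rescaled score point, on T2D
    beta_D: float = math.log(1.69)       # T2D on multi-vessel
    beta_direct: float = math.log(1.04)  # per score point on multi-vessel, not via T2D
    severity_gradient: float = 1.5       # scaling of the linear predictor for 3- vs 2-vessel
    t2d_prevalence_target: float = 0.204
    multivessel_fraction_target: float = 924.0 / 1414.0
    three_vessel_fraction_target: float = 0.5  # among multi-vessel subjects
    covariate_marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    # modest covariate effects (log-odds) on T2D and on multi-vessel disease
    t2d_covariate_betas: dict = field(default_factory=lambda: {
        "age": 0.03, "bmi": 0.08, "male": 0.10})
    mv_covariate_betas: dict = field(default_factory=lambda: {
        "age": 0.035, "male": 0.10, "bmi": 0.01, "current_smoker": 0.05,
        "hypertension": 0.45, "hypercholesterolemia": 0.10})
    missing_rate: float = 0.0
    missing_covariates: tuple[str, ...] = ("bmi", "current_smoker", "hypercholesterolemia")
    missing_mechanism: str = "mcar"      # "mcar" or "mar_age"
    hwe_violation_snps: tuple[int, ...] = ()
    hwe_violation_multiplier: float = 3.0
    info_scores: dict = field(default_factory=dict)  # snp index -> info, default 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.eaf_range
        if lo > hi:
            raise ValueError("eaf_range bounds reversed")
        if not (0.01 < lo and hi < 0.99):
            raise ValueError("eaf_range must lie within (0.01, 0.99)")
        wlo, whi = self.weight_range
        if wlo > whi or wlo <= 0:
            raise ValueError("weight_range must be positive and ordered")
        for name in ("t2d_prevalence_target", "multivessel_fraction_target",
                     "three_vessel_fraction_target"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.severity_gradient < 1:
            raise ValueError("severity_gradient must be >= 1")
        if self.missing_mechanism not in ("mcar", "mar_age"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar_age'")
        if any(i < 0 or i >= self.n_snps for i in self.hwe_violation_snps):
            raise ValueError("hwe_violation_snps index out of range")

    def substream(self, stage: str) -> np.random.Generator:
        """Per-stage RNG so stages can be regenerated independently."""
        stages = ("panel", "genotypes", "phenotypes", "missingness", "extra")
        if stage not in stages:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(stages.index(stage),))
        return np.random.default_rng(ss)

    def truth(self) -> dict:
        d = asdict(self)
        d["covariate_marginals"] = asdict(self.covariate_marginals)
        return d


@dataclass
class SyntheticCohort:
    panel: VariantPanel
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        if len(self.panel) != self.genotypes.n_snps:
            raise ValueError("panel / genotype SNP dimensions disagree")
        if len(self.phenotypes) != self.genotypes.n_subjects:
            raise ValueError("phenotype / genotype subject dimensions disagree")


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def generate_panel(config: SimConfig) -> VariantPanel:
    """Draw a synthetic SNP panel: EAFs and weights uniform in their ranges.

    A random subset of ``n_pleiotropic`` SNPs carries the pleiotropy flag
    (stand-in for loci also associated with other metabolic traits).
    """
    rng = config.substream("panel")
    m = config.n_snps
    eaf = rng.uniform(*config.eaf_range, size=m)
    if config.eaf_range[0] == config.eaf_range[1]:
        eaf = np.full(m, config.eaf_range[0])
    beta = rng.uniform(*config.weight_range, size=m)
    if config.weight_range[0] == config.weight_range[1]:
        beta = np.full(m, config.weight_range[0])
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    pleio = np.zeros(m, dtype=bool)
    if config.n_pleiotropic > 0:
        pleio[rng.choice(m, size=min(config.n_pleiotropic, m), replace=False)] = True
    table = pd.DataFrame({
        "rsid": [f"rs{9000001 + i}" for i in range(m)],
        "chrom": [str(1 + i % 22) for i in range(m)],
        "pos": 1_000_000 + 50_000 * np.arange(m),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "beta": beta,
        "eaf": eaf,
        "pleiotropic": pleio,
    })
    return VariantPanel(table)


def generate_genotypes(panel: VariantPanel, config: SimConfig) -> GenotypeMatrix:
    """Sample hard genotypes under HWE, with optional injected departures.

    Genotype probabilities are ((1-p)^2, 2p(1-p), p^2) for effect-allele
    frequency p; for SNPs listed in ``hwe_violation_snps`` the heterozygote
    probability is multiplied by ``hwe_violation_multiplier`` and the vector
    renormalised.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    rng = config.substream("genotypes")
    n = config.n_subjects
    eafs = panel.eafs
    if np.any(eafs <= 0) or np.any(eafs >= 1):
        raise ValueError("EAFs must lie strictly inside (0, 1)")
    dosages = np.empty((n, len(panel)))
    violated = set(config.hwe_violation_snps)
    for j, p in enumerate(eafs):
        probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        if j in violated:
            if config.hwe_violation_multiplier <= 0:
                raise ValueError("hwe_violation_multiplier must be positive")
            probs[1] *= config.hwe_violation_multiplier
            probs /= probs.sum()
        dosages[:, j] = rng.choice(3, size=n, p=probs)
    info = np.ones(len(panel))
    for j, v in config.info_scores.items():
        info[j] = v
    ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, panel.rsids, info)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_intercept(linpred: np.ndarray, target: float,
                        tol: float = 1e-4) -> float:
    """Bisection on the logit scale so that mean(sigmoid(b0 + linpred)) = target.

    Raises if the target is unattainable within intercepts of magnitude 40
    (i.e. essentially 0 or 1 everywhere).
    """
    lo, hi = -40.0, 40.0
    f = lambda b0: _sigmoid(b0 + linpred).mean() - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"prevalence target {target} unattainable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(f(mid)) < tol and hi - lo < 1e-8:
            break
    return 0.5 * (lo + hi)


def generate_phenotypes(panel: VariantPanel, genotypes: GenotypeMatrix,
                        config: SimConfig) -> pd.DataFrame:
    """Draw covariates, T2D status and vessel counts for each subject.

    T2D follows a logistic model in the (centred) rescaled GRS and
    covariates with intercept calibrated to the prevalence target; the
    multi-vessel indicator follows a logistic model in T2D, the direct GRS
    effect and covariates; among multi-vessel subjects, three- vs two-vessel
    status follows a second logistic whose linear predictor is the first one
    scaled by ``severity_gradient``.
    """
    if np.isnan(genotypes.dosages).any():
        raise ValueError("genotypes must be complete before phenotype generation")
    rng = config.substream("phenotypes")
    n = genotypes.n_subjects
    cm = config.covariate_marginals

    def draw_cont(median, iqr, clip):
        sd = (iqr[1] - iqr[0]) / 1.349
        return np.clip(rng.normal(median, sd, size=n), *clip)

    age = draw_cont(cm.age_median, cm.age_iqr, cm.age_clip)
    bmi = draw_cont(cm.bmi_median, cm.bmi_iqr, cm.bmi_clip)
    male = (rng.random(n) < cm.male).astype(int)
    smoker = (rng.random(n) < cm.current_smoker).astype(int)
    htn = (rng.random(n) < cm.hypertension).astype(int)
    chol = (rng.random(n) < cm.hypercholesterolemia).astype(int)
    famhx = (rng.random(n) < cm.family_history_cad).astype(int)
    prior = (rng.random(n) < cm.prior_cvd).astype(int)
    diagnosis = rng.choice(["UA", "STEMI", "NSTEMI"], size=n,
                           p=np.asarray(cm.diagnosis_fracs) / sum(cm.diagnosis_fracs))

    score = compute_weighted_grs(genotypes, panel).rescaled.to_numpy()
    score_c = score - score.mean()

    cov = {"age": age - age.mean(), "bmi": bmi - bmi.mean(),
           "male": male - male.mean(), "current_smoker": smoker - smoker.mean(),
           "hypertension": htn - htn.mean(),
           "hypercholesterolemia": chol - chol.mean()}

    lp_t2d = config.beta_G * score_c + sum(
        b * cov[k] for k, b in config.t2d_covariate_betas.items())
    b0 = calibrate_intercept(lp_t2d, config.t2d_prevalence_target)
    t2d = (rng.random(n) < _sigmoid(b0 + lp_t2d)).astype(int)

    core = config.beta_direct * score_c + config.beta_D * (t2d - t2d.mean()) + sum(
        b * cov[k] for k, b in config.mv_covariate_betas.items())
    b0_mv = calibrate_intercept(core, config.multivessel_fraction_target)
    mv = (rng.random(n) < _sigmoid(b0_mv + core)).astype(int)

    vessels = np.ones(n, dtype=int)
    mv_idx = np.flatnonzero(mv)
    if mv_idx.size:
        core3 = config.severity_gradient * core[mv_idx]
        b0_3 = calibrate_intercept(core3, config.three_vessel_fraction_target)
        three = rng.random(mv_idx.size) < _sigmoid(b0_3 + core3)
        vessels[mv_idx] = np.where(three, 3, 2)

    return pd.DataFrame({
        "subject_id": genotypes.subject_ids,
        "age": age, "male": male, "bmi": bmi, "current_smoker": smoker,
        "hypertension": htn, "hypercholesterolemia": chol, "t2d": t2d,
        "vessels": vessels, "multi_vessel": mv, "diagnosis": diagnosis,
        "family_history_cad": famhx, "prior_cvd": prior,
        "underwent_angiography": 1, "significant_stenosis": 1,
    })


def inject_missingness(phenotypes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Mask covariate cells at ``missing_rate``; outcomes are never masked.

    MCAR by default; with ``missing_mechanism='mar_age'`` the per-cell
    masking probability depends logistically on age (older subjects more
    likely missing) while keeping the same average rate.
    """
    if config.missing_rate == 0:
        return phenotypes.copy()
    rng = config.substream("missingness")
    out = phenotypes.copy()
    n = len(out)
    for col in config.missing_covariates:
        if col in ("t2d", "vessels", "multi_vessel"):
            raise ValueError("outcomes may not be masked")
        if config.missing_mechanism == "mar_age":
            z = (out["age"].to_numpy() - out["age"].mean()) / out["age"].std()
            p = _sigmoid(z)
            p = p * (config.missing_rate / p.mean())
        else:
            p = np.full(n, config.missing_rate)
        mask = rng.random(n) < np.clip(p, 0, 1)
        out.loc[mask, col] = np.nan
    return out


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Panel -> genotypes -> phenotypes (-> missingness) under one seed."""
    panel = generate_panel(config)
    geno = generate_genotypes(panel, config)
    pheno = generate_phenotypes(panel, geno, config)
    if config.missing_rate > 0:
        pheno = inject_missingness(pheno, config)
    return SyntheticCohort(panel, geno, pheno, config.truth())
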