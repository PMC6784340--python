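"""The causal triangle: GRS -> T2D -> coronary severity.

The expected effect of the score on severity, were it to act purely through
diabetes, is the product of the two component log-odds: beta_E = beta_G x
beta_D, where beta_G is the per-score-point effect on T2D (age-, sex- and
BMI-adjusted) and beta_D the effect of T2D on multi-vessel disease (fully
adjusted).  The observed per-point effect beta_O is compared with beta_E by
a large-sample z test; the attenuation fraction quantifies how much of the
score-severity association is absorbed when T2D status enters the model.

The SE of the product uses the first-order delta method,
se_E = sqrt(beta_G^2 se_D^2 + beta_D^2 se_G^2); a parametric-bootstrap
alternative is available for checking.  The observed and expected effects
come from the same sample; their covariance is ignored in the comparison,
a deliberate approximation in the two-sample style of the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssocResult
from .models import GrsSeverityModel, fit_logistic, _design, _complete_rows, _term_result

__all__ = [
    "expected_effect",
    "expected_effect_bootstrap_se",
    "compare_observed_expected",
    "attenuation_fraction",
    "MediationResult",
    "MediationTriangle",
    "fit_grs_t2d",
]


def expected_effect(beta_G: float, se_G: float, beta_D: float, se_D: float
                    ) -> tuple[float, float]:
    """Expected mediated log-odds beta_G*beta_D and its delta-method SE."""
    if se_G < 0 or se_D < 0:
        raise ValueError("standard errors must be non-negative")
    beta_E = beta_G * beta_D
    se_E = math.sqrt(beta_G ** 2 * se_D ** 2 + beta_D ** 2 * se_G ** 2)
    return beta_E, se_E


def expected_effect_bootstrap_se(beta_G: float, se_G: float, beta_D: float,
                                 se_D: float, n_boot: int = 100_000,
                                 seed: int = 0) -> float:
    """Parametric-bootstrap SE of the product of two independent normals."""
    rng = np.random.default_rng(seed)
    g = rng.normal(beta_G, se_G, n_boot)
    d = rng.normal(beta_D, se_D, n_boot)
    return float(np.std(g * d, ddof=1))


def compare_observed_expected(beta_O: float, se_O: float, beta_E: float,
                              se_E: float) -> tuple[float, float]:
    """z statistic and two-sided p for observed vs expected effect.

    z = (beta_O - beta_E) / sqrt(se_O^2 + se_E^2), referred to the standard
    normal (the large-sample form of the t comparison; at n ~ 1400 the df
    correction moves p by < 0.001).
    """
    denom = math.sqrt(se_O ** 2 + se_E ** 2)
    if denom == 0:
        raise ValueError("both standard errors are zero")
    z = (beta_O - beta_E) / denom
    return z, float(2 * stats.norm.sf(abs(z)))


def attenuation_fraction(beta_without_t2d: float, beta_with_t2d: float) -> float:
    """Fraction of the exposure effect absorbed by adjusting for the mediator."""
    if beta_without_t2d == 0:
        raise ValueError("reference coefficient is zero")
    return 1.0 - beta_with_t2d / beta_without_t2d


def fit_grs_t2d(pheno: pd.DataFrame, grs,
                adjust: tuple[str, ...] = ("age", "male", "bmi")) -> AssocResult:
    """Per-score-point association of the GRS with T2D (logistic, adjusted)."""
    from .grs import GrsResult
    scores = grs.rescaled if isinstance(grs, GrsResult) else pd.Series(grs)
    df = pheno.reset_index(drop=True).copy()
    df["_score"] = scores.reset_index(drop=True).to_numpy()
    df = _complete_rows(df, adjust + ("t2d", "_score"))
    X, names = _design(df, adjust, {"grs": df["_score"].to_numpy()})
    res, conv, sep = fit_logistic(df["t2d"].to_numpy(float), X, names)
    return _term_result(res, names, "grs", "grs_t2d", len(df), conv, sep)


@dataclass
class MediationResult:
    """All six corners of the triangle plus the comparison and attenuation."""

    beta_G: float
    se_G: float
    beta_D: float
    se_D: float
    beta_O: float
    se_O: float
    beta_E: float
    se_E: float
    z_stat: float
    p_compare: float
    attenuation: float

    def or_table(self) -> pd.DataFrame:
        rows = []
        for name, b, s in (("OR_G (GRS->T2D, per point)", self.beta_G, self.se_G),
                           ("OR_D (T2D->multi-vessel)", self.beta_D, self.se_D),
                           ("OR_O (observed GRS->multi-vessel)", self.beta_O, self.se_O),
                           ("OR_E (expected GRS->multi-vessel)", self.beta_E, self.se_E)):
            rows.append({"edge": name, "OR": math.exp(b),
                         "ci_low": math.exp(b - 1.96 * s),
                         "ci_high": math.exp(b + 1.96 * s)})
        out = pd.DataFrame(rows)
        out.attrs["p_compare"] = self.p_compare
        out.attrs["attenuation"] = self.attenuation
        return out

    def summary(self) -> pd.DataFrame:
        return self.or_table()


class MediationTriangle:
    """Fit the three component models and assemble the triangle.

    beta_G: GRS -> T2D per rescaled point, adjusted for age, sex, BMI.
    beta_D: T2D -> multi-vessel, fully adjusted (model 2).
    beta_O: GRS -> multi-vessel per rescaled point, model 2.
    Attenuation compares the model-2 and model-3 per-SD coefficients.
    """

    def __init__(self, pheno: pd.DataFrame, grs):
        self.pheno = pheno
        self.grs = grs

    def fit(self, bootstrap_se: bool = False, seed: int = 0) -> MediationResult:
        rG = fit_grs_t2d(self.pheno, self.grs)
        sev = GrsSeverityModel(self.pheno, self.grs)
        rD = sev.fit("t2d_status", ("model2",)).results[0]
        rO = sev.fit("per_allele", ("model2",)).results[0]
        beta_E, se_E = expected_effect(rG.beta, rG.se, rD.beta, rD.se)
        if bootstrap_se:
            se_E = expected_effect_bootstrap_se(rG.beta, rG.se, rD.beta,
                                                rD.se, seed=seed)
        z, p = compare_observed_expected(rO.beta, rO.se, beta_E, se_E)
        per_sd = sev.fit("per_sd", ("model2", "model3")).results
        atten = attenuation_fraction(per_sd[0].beta, per_sd[1].beta)
        return MediationResult(rG.beta, rG.se, rD.beta, rD.se, rO.beta, rO.se,
                               beta_E, se_E, z, p, atten)
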