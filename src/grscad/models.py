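"""Association analyses for GRS and coronary severity.

Everything here is maximum-likelihood logistic / multinomial-logistic
modelling through statsmodels, organised statsmodels-style: a
:class:`GrsSeverityModel` is built from a phenotype table plus per-subject
scores, and ``fit`` returns a :class:`GrsSeverityResults` carrying
:class:`~grscad.datatypes.AssocResult` terms with a ``summary`` table.

Adjustment tiers (covariate sets):

* model 1 — age, sex, BMI
* model 2 — model 1 + current smoking, hypertension, hypercholesterolemia
* model 3 — model 2 + T2D status

Wald-based p-values and symmetric-on-log-scale CIs are used throughout; a
likelihood-ratio test is used only for the restricted-cubic-spline
nonlinearity test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import AssocResult, GenotypeMatrix, VariantPanel, results_frame
from .grs import GrsResult, assign_tertiles

__all__ = [
    "MODEL_COVARIATES",
    "fit_logistic",
    "baseline_table",
    "GrsSeverityModel",
    "GrsSeverityResults",
    "fit_severity_models",
    "tertile_trend_test",
    "fit_vessel_count_model",
    "SplineFit",
    "rcs_basis",
    "fit_rcs",
    "interaction_and_strata",
    "default_subgroups",
    "single_snp_scan",
]

log = logging.getLogger(__name__)

MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "model1": ("age", "male", "bmi"),
    "model2": ("age", "male", "bmi", "current_smoker", "hypertension",
               "hypercholesterolemia"),
    "model3": ("age", "male", "bmi", "current_smoker", "hypertension",
               "hypercholesterolemia", "t2d"),
}

_SEPARATION_BETA = 15.0
_MAXITER = 100


def _design(pheno: pd.DataFrame, covariates: tuple[str, ...],
            extra: dict[str, np.ndarray] | None = None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pheno))]
    names = ["const"]
    if extra:
        for k, v in extra.items():
            cols.append(np.asarray(v, float))
            names.append(k)
    for c in covariates:
        cols.append(pheno[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str]):
    """ML logistic fit; flags separation (|beta| > 15) and non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=_MAXITER)
    separated = bool(np.any(np.abs(res.params) > _SEPARATION_BETA))
    converged = bool(res.mle_retvals.get("converged", True))
    if separated:
        log.warning("possible separation in logistic fit (terms %s)", names)
    return res, converged, separated


def _term_result(res, names, term, model_tag, n, converged, separated,
                 rename: str | None = None) -> AssocResult:
    i = names.index(term)
    return AssocResult(
        term=rename or term, beta=float(res.params[i]), se=float(res.bse[i]),
        p=float(res.pvalues[i]), model_tag=model_tag, n_used=int(n),
        converged=converged, separation=separated)


def _complete_rows(pheno: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    sub = pheno.dropna(subset=[c for c in cols if c in pheno.columns])
    if len(sub) < len(pheno):
        log.info("dropping %d incomplete rows for model fit",
                 len(pheno) - len(sub))
    return sub


# ---------------------------------------------------------------------------
# baseline descriptives

def baseline_table(pheno: pd.DataFrame,
                   continuous: tuple[str, ...] = ("age", "bmi"),
                   normal_vars: tuple[str, ...] = (),
                   yates: bool = False) -> pd.DataFrame:
    """Baseline characteristics by single- vs multi-vessel disease.

    Continuous variables are summarised as median (IQR) and compared by
    Mann-Whitney U (or t test for variables listed in ``normal_vars``);
    categorical variables as n (%) with a chi-square test (Yates continuity
    correction off by default).
    """
    if "multi_vessel" not in pheno.columns:
        raise ValueError("multi_vessel indicator required")
    g0 = pheno[pheno["multi_vessel"] == 0]
    g1 = pheno[pheno["multi_vessel"] == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("a severity stratum is empty")
    rows = []

    def fmt_cont(s: pd.Series) -> str:
        q = s.quantile([0.25, 0.5, 0.75])
        return f"{q[0.5]:.1f} ({q[0.25]:.1f}-{q[0.75]:.1f})"

    for var in continuous:
        a, b = g0[var].dropna(), g1[var].dropna()
        if var in normal_vars:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            test = "t"
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            test = "mann-whitney"
        rows.append({"variable": var, "total": fmt_cont(pheno[var].dropna()),
                     "single_vessel": fmt_cont(a), "multi_vessel": fmt_cont(b),
                     "p": float(p), "test": test})

    cat_vars = [c for c in ("male", "current_smoker", "hypertension", "t2d",
                            "hypercholesterolemia", "family_history_cad",
                            "prior_cvd", "diagnosis") if c in pheno.columns]
    for var in cat_vars:
        tab = pd.crosstab(pheno[var], pheno["multi_vessel"])
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=yates)

        def fmt_cat(s: pd.Series) -> str:
            s = s.dropna()
            if var == "diagnosis":
                return "; ".join(f"{k}: {v} ({100*v/len(s):.1f})"
                                 for k, v in s.value_counts().items())
            k = int((s == 1).sum())
            return f"{k} ({100*k/len(s):.1f})"

        rows.append({"variable": var, "total": fmt_cat(pheno[var]),
                     "single_vessel": fmt_cat(g0[var]),
                     "multi_vessel": fmt_cat(g1[var]),
                     "p": float(p), "test": "chi2"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# severity models (Model -> Results)

def _scores_series(grs) -> pd.Series:
    if isinstance(grs, GrsResult):
        return grs.rescaled
    return pd.Series(grs)


@dataclass
class GrsSeverityResults:
    """Results container: one AssocResult per fitted exposure term."""

    results: list[AssocResult]
    exposure: str
    score_sd: float | None = None
    trend: AssocResult | None = None
    tertile_sizes: tuple[int, int, int] | None = None

    def summary(self) -> pd.DataFrame:
        out = results_frame(self.results)
        if self.trend is not None:
            out.attrs["p_trend"] = {self.trend.model_tag: self.trend.p}
        return out


class GrsSeverityModel:
    """Multi-vessel disease (vs single-vessel) modelled on a GRS exposure.

    Parameters
    ----------
    pheno : phenotype table with ``multi_vessel`` and the model covariates
    grs : GrsResult or per-subject rescaled-score Series aligned to pheno
    """

    def __init__(self, pheno: pd.DataFrame, grs=None):
        self.pheno = pheno.reset_index(drop=True)
        self.scores = (None if grs is None
                       else _scores_series(grs).reset_index(drop=True))

    def fit(self, exposure: str = "per_allele",
            models: tuple[str, ...] = ("model1", "model2", "model3"),
            ) -> GrsSeverityResults:
        """Fit the nested adjustment tiers for one exposure coding.

        exposure: 'per_allele' (rescaled score), 'per_sd' (score / sample
        SD), 'tertile' (two contrasts vs the low tertile plus a trend p), or
        't2d_status' (model 3, which adjusts for T2D, is skipped).
        """
        if exposure not in ("per_allele", "per_sd", "tertile", "t2d_status"):
            raise ValueError(f"unknown exposure {exposure!r}")
        if exposure != "t2d_status" and self.scores is None:
            raise ValueError("scores required for GRS exposures")
        results: list[AssocResult] = []
        trend = None
        sizes = None
        sd = float(self.scores.std(ddof=1)) if self.scores is not None else None

        for tag in models:
            if tag == "model3" and exposure == "t2d_status":
                continue
            covs = MODEL_COVARIATES[tag]
            df = self.pheno.copy()
            if self.scores is not None:
                df["_score"] = self.scores.to_numpy()
            need = covs + (("multi_vessel", "_score") if self.scores is not None
                           else ("multi_vessel",))
            df = _complete_rows(df, need)
            y = df["multi_vessel"].to_numpy(float)

            if exposure == "t2d_status":
                covs = tuple(c for c in covs if c != "t2d")
                X, names = _design(df, covs, {"t2d_status": df["t2d"].to_numpy(float)})
                res, conv, sep = fit_logistic(y, X, names)
                results.append(_term_result(res, names, "t2d_status", tag,
                                            len(df), conv, sep))
            elif exposure in ("per_allele", "per_sd"):
                x = df["_score"].to_numpy()
                if exposure == "per_sd":
                    x = x / sd
                X, names = _design(df, covs, {"grs": x})
                res, conv, sep = fit_logistic(y, X, names)
                results.append(_term_result(res, names, "grs", tag, len(df),
                                            conv, sep, rename=f"grs_{exposure}"))
            else:  # tertile
                labels, sizes = assign_tertiles(
                    pd.Series(df["_score"].to_numpy(),
                              index=df["subject_id"].to_numpy()))
                med = (labels == "medium").astype(float).to_numpy()
                high = (labels == "high").astype(float).to_numpy()
                X, names = _design(df, covs, {"tertile_medium": med,
                                              "tertile_high": high})
                res, conv, sep = fit_logistic(y, X, names)
                for t in ("tertile_medium", "tertile_high"):
                    results.append(_term_result(res, names, t, tag, len(df),
                                                conv, sep))
                idx = np.where(labels == "low", 0.0,
                               np.where(labels == "medium", 1.0, 2.0))
                Xt, nt = _design(df, covs, {"tertile_index": idx})
                rt, conv_t, sep_t = fit_logistic(y, Xt, nt)
                trend = _term_result(rt, nt, "tertile_index", tag, len(df),
                                     conv_t, sep_t)
        return GrsSeverityResults(results, exposure, sd, trend, sizes)


def fit_severity_models(pheno: pd.DataFrame, grs, exposure: str = "per_allele",
                        models: tuple[str, ...] = ("model1", "model2", "model3"),
                        ) -> list[AssocResult]:
    """Functional wrapper around :class:`GrsSeverityModel`."""
    return GrsSeverityModel(pheno, grs).fit(exposure, models).results


def tertile_trend_test(pheno: pd.DataFrame, grs,
                       model_tag: str = "model2") -> AssocResult:
    """Wald p for an ordinal 0/1/2 tertile-index term (trend across tertiles)."""
    r = GrsSeverityModel(pheno, grs).fit("tertile", (model_tag,))
    assert r.trend is not None
    return r.trend


# ---------------------------------------------------------------------------
# multinomial vessel-count model

def fit_vessel_count_model(pheno: pd.DataFrame, grs,
                           models: tuple[str, ...] = ("model1", "model2", "model3"),
                           per_sd: bool = True) -> list[AssocResult]:
    """Multinomial logit of vessel count (1/2/3; one-vessel reference).

    Returns the GRS term (per SD by default) for the 2-vs-1 and 3-vs-1
    contrasts under each adjustment tier.
    """
    scores = _scores_series(grs).reset_index(drop=True)
    pheno = pheno.reset_index(drop=True)
    cats = sorted(pheno["vessels"].dropna().unique())
    if len(cats) < 2:
        raise ValueError("vessel-count outcome has fewer than 2 categories")
    sd = float(scores.std(ddof=1))
    out: list[AssocResult] = []
    for tag in models:
        covs = MODEL_COVARIATES[tag]
        df = pheno.copy()
        df["_score"] = scores.to_numpy() / (sd if per_sd else 1.0)
        df = _complete_rows(df, covs + ("vessels", "_score"))
        y = pd.Categorical(df["vessels"], categories=cats).codes
        X, names = _design(df, covs, {"grs": df["_score"].to_numpy()})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, X).fit(disp=0, maxiter=_MAXITER)
        conv = bool(res.mle_retvals.get("converged", True))
        i = names.index("grs")
        # column k of params is the contrast (category k+1) vs reference
        for k, cat in enumerate(cats[1:]):
            beta = float(res.params.iloc[i, k] if hasattr(res.params, "iloc")
                         else res.params[i, k])
            se = float(res.bse.iloc[i, k] if hasattr(res.bse, "iloc")
                       else res.bse[i, k])
            p = float(2 * stats.norm.sf(abs(beta / se)))
            out.append(AssocResult(
                term=f"grs_{int(cat)}v{int(cats[0])}", beta=beta, se=se, p=p,
                model_tag=tag, n_used=len(df), converged=conv,
                separation=abs(beta) > _SEPARATION_BETA))
    return out


# ---------------------------------------------------------------------------
# restricted cubic spline dose-response

_KNOT_QUANTILES = {3: (0.10, 0.50, 0.90),
                   4: (0.05, 0.35, 0.65, 0.95),
                   5: (0.05, 0.275, 0.50, 0.725, 0.95)}


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails), k-1 columns.

    First column is x itself; the k-2 nonlinear columns use the standard
    truncated-power construction normalised by the squared boundary-knot
    span, so the fit is linear beyond the boundary knots.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    k = len(t)
    if k < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("need >= 3 strictly increasing knots")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    plus = lambda v: np.clip(v, 0, None) ** 3
    for j in range(k - 2):
        term = (plus(x - t[j])
                - plus(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + plus(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    knots: np.ndarray
    params: np.ndarray
    nonlinearity_p: float
    curve: pd.DataFrame  # score, OR, ci_low, ci_high (vs reference score)
    reference: float
    n_used: int


def fit_rcs(pheno: pd.DataFrame, grs, n_knots: int = 4,
            model_tag: str = "model2", grid_size: int = 100) -> SplineFit:
    """Dose-response of multi-vessel risk on the score via restricted cubic splines.

    Knots sit at the conventional quantiles (e.g. 5/35/65/95% for 4 knots).
    The nonlinearity p comes from a likelihood-ratio test of the k-2
    nonlinear basis terms against the purely linear model; the odds-ratio
    curve is referenced to the cohort median (OR = 1 there by construction).
    """
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError("n_knots must be one of 3, 4, 5")
    scores = _scores_series(grs).reset_index(drop=True)
    df = pheno.reset_index(drop=True).copy()
    df["_score"] = scores.to_numpy()
    covs = MODEL_COVARIATES[model_tag]
    df = _complete_rows(df, covs + ("multi_vessel", "_score"))
    x = df["_score"].to_numpy()
    knots = np.quantile(x, _KNOT_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("coincident knots; score distribution too degenerate")
    B = rcs_basis(x, knots)
    y = df["multi_vessel"].to_numpy(float)

    extra = {f"rcs{j}": B[:, j] for j in range(B.shape[1])}
    X, names = _design(df, covs, extra)
    res, _, _ = fit_logistic(y, X, names)
    Xlin, nlin = _design(df, covs, {"rcs0": B[:, 0]})
    res_lin, _, _ = fit_logistic(y, Xlin, nlin)
    df_nl = B.shape[1] - 1
    lr = 2 * (res.llf - res_lin.llf)
    nonlin_p = float(stats.chi2.sf(max(lr, 0.0), df_nl))

    ref = float(np.median(x))
    grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), grid_size)
    idx = [names.index(f"rcs{j}") for j in range(B.shape[1])]
    beta_s = res.params[idx]
    cov_s = res.cov_params()[np.ix_(idx, idx)]
    delta = rcs_basis(grid, knots) - rcs_basis(np.full_like(grid, ref), knots)
    eta = delta @ beta_s
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, cov_s, delta))
    curve = pd.DataFrame({
        "score": grid, "OR": np.exp(eta),
        "ci_low": np.exp(eta - 1.96 * se), "ci_high": np.exp(eta + 1.96 * se)})
    return SplineFit(knots, res.params, nonlin_p, curve, ref, len(df))


# ---------------------------------------------------------------------------
# interaction and stratified analyses

def default_subgroups(pheno: pd.DataFrame) -> list[tuple[str, pd.Series, tuple[str, ...]]]:
    """Standard subgroup definitions: (name, indicator, covariates-to-drop).

    Stratified fits adjust for age and sex except when stratifying on age
    or sex, in which case that covariate is dropped.
    """
    subs = [
        ("age_ge60", pheno["age"] >= 60, ("age",)),
        ("male", pheno["male"] == 1, ("male",)),
        ("bmi_ge24", pheno["bmi"] >= 24, ()),
        ("current_smoker", pheno["current_smoker"] == 1, ()),
        ("hypertension", pheno["hypertension"] == 1, ()),
        ("hypercholesterolemia", pheno["hypercholesterolemia"] == 1, ()),
        ("t2d", pheno["t2d"] == 1, ()),
    ]
    for opt in ("family_history_cad", "prior_cvd"):
        if opt in pheno.columns:
            subs.append((opt, pheno[opt] == 1, ()))
    return subs


def interaction_and_strata(pheno: pd.DataFrame, grs,
                           subgroups=None,
                           adjust: tuple[str, ...] = ("age", "male"),
                           ) -> pd.DataFrame:
    """Per-SD GRS odds ratios within each stratum plus a Wald interaction p.

    Each factor contributes two stratum fits (factor present / absent,
    age- and sex-adjusted minus the stratifier itself) and one pooled fit
    with a GRS x factor product term whose Wald p is the interaction test.
    Degenerate strata (single outcome level) are reported and skipped.
    """
    scores = _scores_series(grs).reset_index(drop=True)
    pheno = pheno.reset_index(drop=True)
    sd = float(scores.std(ddof=1))
    x_all = scores.to_numpy() / sd
    if subgroups is None:
        subgroups = default_subgroups(pheno)
    rows = []
    for name, flag, drops in subgroups:
        flag = pd.Series(flag).reset_index(drop=True).astype(bool)
        covs = tuple(c for c in adjust if c not in drops)
        # pooled model with product term
        X, names = _design(pheno, covs, {
            "grs": x_all, "factor": flag.to_numpy(float),
            "grs_x_factor": x_all * flag.to_numpy(float)})
        res, conv, sep = fit_logistic(pheno["multi_vessel"].to_numpy(float), X, names)
        p_int = float(res.pvalues[names.index("grs_x_factor")])
        for level, mask in ((1, flag), (0, ~flag)):
            sub = pheno[mask.to_numpy()]
            if sub["multi_vessel"].nunique() < 2 or len(sub) < len(covs) + 3:
                log.warning("subgroup %s=%d degenerate; skipped", name, level)
                rows.append({"factor": name, "level": level, "n": len(sub),
                             "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "p": np.nan, "p_interaction": p_int})
                continue
            Xs, ns = _design(sub, covs, {"grs": x_all[mask.to_numpy()]})
            rs, conv_s, sep_s = fit_logistic(sub["multi_vessel"].to_numpy(float),
                                             Xs, ns)
            ar = _term_result(rs, ns, "grs", f"stratum:{name}={level}",
                              len(sub), conv_s, sep_s)
            lo, hi = ar.ci95
            rows.append({"factor": name, "level": level, "n": len(sub),
                         "OR": ar.or_, "ci_low": lo, "ci_high": hi,
                         "p": ar.p, "p_interaction": p_int})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-SNP scan

def single_snp_scan(genotypes: GenotypeMatrix, panel: VariantPanel,
                    pheno: pd.DataFrame,
                    adjust: tuple[str, ...] = ("age", "male")) -> pd.DataFrame:
    """Additive per-allele association of each SNP with multi-vessel disease.

    Age- and sex-adjusted; no multiplicity adjustment (per-SNP display).
    Monomorphic SNPs are skipped with a note.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    pheno = pheno.reset_index(drop=True)
    y = pheno["multi_vessel"].to_numpy(float)
    rows = []
    for j, rsid in enumerate(panel.rsids):
        d = genotypes.dosages[:, j]
        ok = ~np.isnan(d)
        if np.nanstd(d) == 0:
            log.info("SNP %s monomorphic; skipped in scan", rsid)
            rows.append({"rsid": rsid, "OR": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "n": int(ok.sum()),
                         "note": "monomorphic"})
            continue
        sub = pheno[ok]
        X, names = _design(sub, adjust, {"dosage": d[ok]})
        res, conv, sep = fit_logistic(y[ok], X, names)
        ar = _term_result(res, names, "dosage", "snp_scan", int(ok.sum()),
                          conv, sep)
        lo, hi = ar.ci95
        rows.append({"rsid": rsid, "OR": ar.or_, "ci_low": lo, "ci_high": hi,
                     "p": ar.p, "n": ar.n_used, "note": ""})
    return pd.DataFrame(rows)
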