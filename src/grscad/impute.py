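"""Chained-equation multiple imputation and Rubin's-rules pooling.

Missing covariates are imputed m times by cycling per-variable regressions:
predictive-mean matching (5 donors) for continuous variables and logistic
Bernoulli draws for binary ones, with all other baseline characteristics
(plus outcome and score, which are themselves never imputed) as predictors.
Per-imputation model fits are pooled with Rubin's rules: the total variance
is the mean within-imputation variance plus (1 + 1/m) times the
between-imputation variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssocResult

__all__ = ["ImputationSet", "PooledResult", "mice_impute", "rubin_pool",
           "pool_results", "fit_pooled"]

_PMM_DONORS = 5


@dataclass
class ImputationSet:
    tables: list[pd.DataFrame]
    methods: dict[str, str]
    cycles: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.tables)


@dataclass
class PooledResult:
    beta: float
    within_var: float
    between_var: float
    m: int

    @property
    def total_var(self) -> float:
        return self.within_var + (1 + 1 / self.m) * self.between_var

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    @property
    def p(self) -> float:
        if self.se == 0:
            return 1.0
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))


def _is_binary(s: pd.Series) -> bool:
    vals = set(s.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float = 1e-6) -> np.ndarray:
    XtX = X.T @ X + lam * np.eye(X.shape[1])
    return np.linalg.solve(XtX, X.T @ y)


def _logistic_irls(X: np.ndarray, y: np.ndarray, maxiter: int = 50,
                   lam: float = 1e-6) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-8, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        new = np.linalg.solve(X.T @ Xw + lam * np.eye(X.shape[1]), Xw.T @ z)
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    return beta


def mice_impute(pheno: pd.DataFrame, m: int = 9, cycles: int = 10,
                seed: int = 0,
                predictors: tuple[str, ...] | None = None,
                never_impute: tuple[str, ...] = ("t2d", "vessels",
                                                 "multi_vessel"),
                ) -> ImputationSet:
    """Multiple imputation by chained equations; m completed tables.

    Continuous variables use predictive-mean matching (ridge-stabilised
    linear predictor, 5 nearest observed donors, one drawn at random);
    binary variables use a logistic fit and a Bernoulli draw.  Outcome
    columns may serve as predictors but are never imputed; rows must be
    complete in them.  Deterministic under ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    numeric = [c for c in pheno.columns
               if pd.api.types.is_numeric_dtype(pheno[c])]
    targets = [c for c in numeric
               if pheno[c].isna().any() and c not in never_impute]
    for c in never_impute:
        if c in pheno.columns and pheno[c].isna().any():
            raise ValueError(f"outcome column {c!r} contains missing values")
    for c in targets:
        if pheno[c].isna().all():
            raise ValueError(f"column {c!r} is 100% missing; cannot impute")
    if predictors is None:
        predictors = tuple(c for c in numeric if c != "subject_id")
    methods = {c: ("logistic" if _is_binary(pheno[c]) else "pmm")
               for c in targets}
    if not targets:
        return ImputationSet([pheno.copy() for _ in range(m)], methods,
                             cycles, seed)

    root = np.random.SeedSequence(seed)
    tables = []
    for child in root.spawn(m):
        rng = np.random.default_rng(child)
        df = pheno.copy()
        # initial fill: random draws from the observed values
        for c in targets:
            obs = df[c].dropna().to_numpy()
            nmiss = int(df[c].isna().sum())
            df.loc[df[c].isna(), c] = rng.choice(obs, size=nmiss)
        miss_mask = {c: pheno[c].isna().to_numpy() for c in targets}
        for _ in range(cycles):
            for c in targets:
                mask = miss_mask[c]
                preds = [p for p in predictors if p != c]
                X = np.column_stack(
                    [np.ones(len(df))] + [df[p].to_numpy(float) for p in preds])
                y_obs = df.loc[~mask, c].to_numpy(float)
                X_obs, X_mis = X[~mask], X[mask]
                if methods[c] == "logistic":
                    beta = _logistic_irls(X_obs, y_obs)
                    p_mis = 1 / (1 + np.exp(-np.clip(X_mis @ beta, -30, 30)))
                    df.loc[mask, c] = (rng.random(mask.sum()) < p_mis).astype(float)
                else:  # predictive-mean matching
                    beta = _ridge_solve(X_obs, y_obs)
                    yhat_obs = X_obs @ beta
                    yhat_mis = X_mis @ beta
                    order = np.argsort(yhat_obs, kind="stable")
                    sorted_hat = yhat_obs[order]
                    pos = np.searchsorted(sorted_hat, yhat_mis)
                    draws = np.empty(mask.sum())
                    for i, (pm, ps) in enumerate(zip(yhat_mis, pos)):
                        lo = max(0, ps - _PMM_DONORS)
                        hi = min(len(sorted_hat), ps + _PMM_DONORS)
                        cand = order[lo:hi]
                        dist = np.abs(yhat_obs[cand] - pm)
                        donors = cand[np.argsort(dist, kind="stable")[:_PMM_DONORS]]
                        draws[i] = y_obs[donors[rng.integers(0, len(donors))]]
                    df.loc[mask, c] = draws
        tables.append(df)
    return ImputationSet(tables, methods, cycles, seed)


def rubin_pool(betas, ses) -> PooledResult:
    """Combine per-imputation estimates: Rubin's rules."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be equal-length vectors")
    m = len(betas)
    if m < 1:
        raise ValueError("need at least one imputation")
    within = float(np.mean(ses ** 2))
    between = float(np.var(betas, ddof=1)) if m > 1 else 0.0
    return PooledResult(float(betas.mean()), within, between, m)


def pool_results(results: list[AssocResult]) -> AssocResult:
    """Pool m AssocResults for the same term into one pooled AssocResult."""
    if not results:
        raise ValueError("nothing to pool")
    terms = {r.term for r in results}
    if len(terms) != 1:
        raise ValueError(f"cannot pool different terms: {terms}")
    pooled = rubin_pool([r.beta for r in results], [r.se for r in results])
    r0 = results[0]
    return AssocResult(term=r0.term, beta=pooled.beta, se=pooled.se,
                       p=pooled.p, model_tag=r0.model_tag, n_used=r0.n_used,
                       pooled=True, m_imputations=pooled.m)


def fit_pooled(imp: ImputationSet, fit_fn) -> list[AssocResult]:
    """Apply a fitting function to each completed table and pool term-wise.

    ``fit_fn`` maps a completed phenotype table to a list of AssocResults;
    results are grouped by (term, model_tag) in first-table order.
    """
    per_table = [fit_fn(t) for t in imp.tables]
    keys = [(r.term, r.model_tag) for r in per_table[0]]
    out = []
    for k in keys:
        group = [r for fits in per_table for r in fits
                 if (r.term, r.model_tag) == k]
        out.append(pool_results(group))
    return out
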