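"""Simulation-based power for a case-control logistic association.

Replicates a genetic-score power calculation by direct simulation: scores
are drawn normal with the empirical SD, the binary outcome follows a
logistic model whose intercept is calibrated so the expected case fraction
matches the study, and each replicate is tested with a univariable logistic
Wald test.  The closed-form Wald approximation is emitted alongside, since
simulation and approximation bracket what dedicated power tools report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerResult", "estimate_power", "closed_form_power",
           "newton_logistic_2p"]


@dataclass(frozen=True)
class PowerResult:
    reps: int
    alpha: float
    true_or: float
    n: int
    case_fraction: float
    score_sd: float
    power_hat: float
    seed: int

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power_hat * (1 - self.power_hat) / self.reps)


def newton_logistic_2p(x: np.ndarray, y: np.ndarray,
                       maxiter: int = 50, tol: float = 1e-10
                       ) -> tuple[float, float, float]:
    """Newton-Raphson fit of y ~ 1 + x; returns (beta, se_beta, intercept).

    A minimal two-parameter solver used inside the replicate loop; agrees
    with the general ML fit to full precision (asserted in tests).
    """
    b0, b1 = 0.0, 0.0
    for _ in range(maxiter):
        eta = np.clip(b0 + b1 * x, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        g0 = np.sum(y - mu)
        g1 = np.sum((y - mu) * x)
        h00 = np.sum(w)
        h01 = np.sum(w * x)
        h11 = np.sum(w * x * x)
        det = h00 * h11 - h01 * h01
        if det <= 0:
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if abs(d0) < tol and abs(d1) < tol:
            break
    eta = np.clip(b0 + b1 * x, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    w = mu * (1 - mu)
    h00 = np.sum(w)
    h01 = np.sum(w * x)
    h11 = np.sum(w * x * x)
    det = h00 * h11 - h01 * h01
    se = math.sqrt(h00 / det) if det > 0 else math.inf
    return b1, se, b0


def _calibrate_normal_intercept(beta: float, sd: float, target: float) -> float:
    """Intercept so that E[sigmoid(b0 + beta*X)] = target for X ~ N(0, sd^2).

    Gauss-Hermite quadrature on the normal expectation, bisection on b0.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    x = nodes * sd

    def prev(b0: float) -> float:
        return float(np.sum(weights / (1 + np.exp(-(b0 + beta * x))))
                     / np.sum(weights))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_power(n: int = 1414, case_fraction: float = 924 / 1414,
                   score_sd: float = 3.81, true_or: float = 1.04,
                   alpha: float = 0.05, reps: int = 2000,
                   seed: int = 0) -> PowerResult:
    """Monte-Carlo power of the two-sided Wald test at level ``alpha``.

    Each replicate draws n scores ~ N(0, score_sd^2), assigns the outcome
    from a logistic model with slope ln(true_or) and intercept calibrated
    to the case fraction, fits the univariable logistic, and records
    whether the Wald p falls below alpha.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie strictly in (0, 1)")
    beta = math.log(true_or)
    b0 = _calibrate_normal_intercept(beta, score_sd, case_fraction)
    z_crit = stats.norm.isf(alpha / 2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        x = rng.normal(0.0, score_sd, n)
        p = 1 / (1 + np.exp(-(b0 + beta * x)))
        y = (rng.random(n) < p).astype(float)
        if y.min() == y.max():      # degenerate replicate: no information
            continue
        bhat, se, _ = newton_logistic_2p(x, y)
        if se > 0 and abs(bhat / se) > z_crit:
            hits += 1
    return PowerResult(reps, alpha, true_or, n, case_fraction, score_sd,
                       hits / reps, seed)


def closed_form_power(n: int, case_fraction: float, score_sd: float,
                      true_or: float, alpha: float = 0.05) -> float:
    """Wald approximation: Phi(|beta| sd sqrt(n p(1-p)) - z_{1-alpha/2})."""
    beta = abs(math.log(true_or))
    z = stats.norm.isf(alpha / 2)
    ncp = beta * score_sd * math.sqrt(n * case_fraction * (1 - case_fraction))
    return float(stats.norm.cdf(ncp - z))
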