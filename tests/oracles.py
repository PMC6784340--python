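"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
enumeration for the Hardy-Weinberg test, closed-form 2x2 odds ratios, and
hand arithmetic, so the implementation is checked against something it
does not share code with.
"""

from fractions import Fraction
from math import factorial, sqrt


def hwe_exact_oracle(a: int, b: int, c: int) -> float:
    """Two-sided exact HWE p by exhaustive enumeration in exact arithmetic.

    a/b/c = hom-effect / het / hom-other counts.  Enumerates every
    heterozygote count consistent with the observed allele counts, computes
    each configuration's conditional probability as an exact rational, and
    sums those <= the observed one.
    """
    n = a + b + c
    n_eff = 2 * a + b
    n_oth = 2 * c + b
    rare = min(n_eff, n_oth)
    if rare == 0:
        return 1.0
    hets = range(rare % 2, rare + 1, 2)

    def weight(h: int) -> Fraction:
        he = (n_eff - h) // 2
        ho = (n_oth - h) // 2
        return Fraction(factorial(n) * 2 ** h,
                        factorial(he) * factorial(h) * factorial(ho))

    total = sum(weight(h) for h in hets)
    probs = {h: Fraction(weight(h), total) for h in hets}
    p_obs = probs[b]
    return float(sum(p for p in probs.values() if p <= p_obs))


def cross_product_or(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """2x2 odds ratio ad/bc and the SE of its log, sqrt(1/a+1/b+1/c+1/d)."""
    or_ = (a * d) / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, se


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Hand-computed Pearson chi-square statistic for a 2x2 table."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
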