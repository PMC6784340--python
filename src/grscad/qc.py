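"""Variant-level quality control.

Implements the exact test of Hardy-Weinberg equilibrium (conditional on the
observed allele counts, summing the probabilities of all heterozygote
configurations no more probable than the observed one), the panel-wise
Bonferroni threshold, and the variant filter battery (monomorphic, missing
call rate, imputation info score, HWE at two screens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, VariantPanel

__all__ = [
    "HweTestResult",
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "panel_hwe_threshold",
    "apply_variant_filters",
]

# relative tolerance when comparing configuration probabilities; ties count
# toward the p-value
_TIE_REL_TOL = 1e-12


@dataclass(frozen=True)
class HweTestResult:
    n_hom_effect: int
    n_het: int
    n_hom_other: int
    p_exact: float


def hwe_exact_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> HweTestResult:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, every heterozygote count of
    the correct parity is enumerated; the p-value is the summed probability
    of all configurations whose probability does not exceed that of the
    observed configuration (plain, not mid-p, convention).

    The configuration probabilities are computed with the standard stable
    recurrence over adjacent heterozygote counts, so the test is exact for
    any sample size representable in floating point.
    """
    a, b, c = int(n_hom_effect), int(n_het), int(n_hom_other)
    if a < 0 or b < 0 or c < 0:
        raise ValueError("genotype counts must be non-negative")
    n = a + b + c
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_eff = 2 * a + b          # effect-allele count
    n_oth = 2 * c + b
    rare = min(n_eff, n_oth)   # minor-allele count
    if rare == 0:              # monomorphic: only one configuration exists
        return HweTestResult(a, b, c, 1.0)

    # heterozygote counts share the parity of the minor-allele count
    het_min = rare % 2
    hets = np.arange(het_min, rare + 1, 2)

    # unnormalized probabilities via the recurrence
    #   P(het+2)/P(het) = (n_eff-het)(n_oth-het) / ((het+2)(het+1) / 4) ... in
    # the standard form: p_{h+2} = p_h * 4*hom_e*hom_o / ((h+2)(h+1))
    # where hom_e=(n_eff-h)/2, hom_o=(n_oth-h)/2 at het=h.
    probs = np.empty(len(hets))
    probs[0] = 1.0
    for i in range(len(hets) - 1):
        h = hets[i]
        hom_e = (n_eff - h) // 2
        hom_o = (n_oth - h) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_e * hom_o / ((h + 2.0) * (h + 1.0))
        # renormalize on the fly to avoid overflow at large n
        if probs[i + 1] > 1e290:
            probs /= probs[i + 1]
    probs /= probs.sum()

    p_obs = probs[(b - het_min) // 2]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    return HweTestResult(a, b, c, min(p, 1.0))


def panel_hwe_threshold(n_snps: int, family_alpha: float = 0.05) -> float:
    """Bonferroni per-SNP significance threshold ``family_alpha / n_snps``."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / n_snps


@dataclass
class QcThresholds:
    """Variant-filter thresholds.

    max_missing_rate: drop SNPs with missing call rate >= this (default 0.05).
    min_info: drop SNPs with imputation info score < this (strict; default 0.7).
    hwe_p_floor: permissive HWE screen; drop if exact p < this (default 1e-5).
    hwe_family_alpha: panel-wise Bonferroni screen; drop if exact
        p < hwe_family_alpha / n_snps (default 0.05). Set to None to disable.
    hard_call_max_distance: max per-call distance to an integer for dosages
        to be hard-called for the HWE test (default 0.1).
    """

    max_missing_rate: float = 0.05
    min_info: float = 0.7
    hwe_p_floor: float = 1e-5
    hwe_family_alpha: float | None = 0.05
    hard_call_max_distance: float = 0.1

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_info", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.hwe_family_alpha is not None and not 0 < self.hwe_family_alpha < 1:
            raise ValueError("hwe_family_alpha must lie in (0, 1) or be None")


@dataclass
class QcReport:
    """Per-SNP QC record plus the thresholds that produced it."""

    table: pd.DataFrame  # rsid, missing_rate, info, hwe_p, pass, fail_reasons
    thresholds: QcThresholds
    notes: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            t = self.thresholds
            fh.write(f"# max_missing_rate={t.max_missing_rate}\n")
            fh.write(f"# min_info={t.min_info}\n")
            fh.write(f"# hwe_p_floor={t.hwe_p_floor}\n")
            fh.write(f"# hwe_family_alpha={t.hwe_family_alpha}\n")
            for note in self.notes:
                fh.write(f"# note: {note}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def apply_variant_filters(
    panel: VariantPanel,
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
) -> tuple[VariantPanel, QcReport]:
    """Apply the variant-filter battery; return the surviving panel + report.

    Rules, in report order: monomorphic after rounding; missing call rate >=
    ``max_missing_rate``; info score < ``min_info`` (strict inequality, so
    info = 0.70 is kept); exact HWE p below the permissive floor; exact HWE p
    below the panel-wise Bonferroni threshold.  HWE is computed on hard calls
    obtained by rounding dosages; when dosages are materially fractional the
    HWE screens are skipped for the whole matrix with a logged note.
    Filtering is idempotent.
    """
    thr = thresholds or QcThresholds()
    if panel.rsids != genotypes.rsids:
        raise ValueError("panel and genotype matrix are not aligned")

    n_snps = len(panel)
    bonf = (panel_hwe_threshold(n_snps, thr.hwe_family_alpha)
            if thr.hwe_family_alpha is not None else None)
    notes: list[str] = []

    hard = genotypes.hard_calls(thr.hard_call_max_distance)
    if hard is None:
        notes.append("fractional dosages: HWE screens skipped")

    rows = []
    miss = genotypes.missing_rate()
    for j, rsid in enumerate(panel.rsids):
        reasons: list[str] = []
        hwe_p = math.nan
        if hard is not None:
            g = hard[:, j]
            g = g[g >= 0]
            counts = [(g == 2).sum(), (g == 1).sum(), (g == 0).sum()]
            dosage_sum = 2 * counts[0] + counts[1]
            if min(dosage_sum, 2 * len(g) - dosage_sum) == 0:
                reasons.append("monomorphic")
            else:
                hwe_p = hwe_exact_test(*counts).p_exact
                if hwe_p < thr.hwe_p_floor:
                    reasons.append(f"hwe_p<{thr.hwe_p_floor:g}")
                if bonf is not None and hwe_p < bonf:
                    reasons.append(f"hwe_p<bonferroni({bonf:.3g})")
        if miss[j] >= thr.max_missing_rate:
            reasons.append(f"missing_rate>={thr.max_missing_rate:g}")
        if genotypes.info[j] < thr.min_info:
            reasons.append(f"info<{thr.min_info:g}")
        rows.append({
            "rsid": rsid,
            "missing_rate": float(miss[j]),
            "info": float(genotypes.info[j]),
            "hwe_p": hwe_p,
            "pass": not reasons,
            "fail_reasons": ";".join(reasons),
        })

    report = pd.DataFrame(rows)
    keep = report.loc[report["pass"], "rsid"].tolist()
    return panel.subset(keep), QcReport(report, thr, notes)
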