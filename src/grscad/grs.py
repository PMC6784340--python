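"""Construction of weighted, rescaled and unweighted genetic risk scores.

The weighted score is the sum over panel SNPs of (published per-allele
log-odds) x (risk-allele dosage).  To express the score in risk-allele units
it is rescaled by n_snps / sum(beta), so that with equal weights the rescaled
score equals the plain risk-allele count and one score point corresponds to
roughly one risk allele.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, VariantPanel

__all__ = [
    "Orientation",
    "AlleleAlignmentError",
    "align_alleles",
    "GrsResult",
    "compute_weighted_grs",
    "compute_unweighted_grs",
    "exclude_pleiotropic",
    "assign_tertiles",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Orientation(enum.Enum):
    """How a VCF record's alt-allele dosage maps to effect-allele dosage."""

    AS_IS = "as_is"                          # alt IS the effect allele
    COMPLEMENTED_DOSAGE = "complemented_dosage"  # ref is the effect allele: d_eff = 2 - d_alt
    STRAND_FLIP_AS_IS = "strand_flip_as_is"
    STRAND_FLIP_COMPLEMENTED = "strand_flip_complemented"


class AlleleAlignmentError(ValueError):
    pass


def align_alleles(vcf_ref: str, vcf_alt: str, effect_allele: str,
                  other_allele: str, rsid: str = "?") -> Orientation:
    """Resolve how the weights-file alleles map onto a VCF record.

    Palindromic (A/T or C/G) SNPs are intrinsically strand-ambiguous, so
    they resolve only in the two non-flipped frames; a flipped match for a
    palindromic SNP is indistinguishable from the non-flipped one and is
    treated as unresolvable if the direct frames fail.
    """
    for a in (vcf_ref, vcf_alt, effect_allele, other_allele):
        if a not in _COMPLEMENT:
            raise AlleleAlignmentError(
                f"{rsid}: only single-nucleotide alleles supported, got {a!r}")
    pair = (vcf_ref, vcf_alt)
    if pair == (other_allele, effect_allele):
        return Orientation.AS_IS
    if pair == (effect_allele, other_allele):
        return Orientation.COMPLEMENTED_DOSAGE
    palindromic = effect_allele == _COMPLEMENT[other_allele]
    if not palindromic:
        eff_c, oth_c = _COMPLEMENT[effect_allele], _COMPLEMENT[other_allele]
        if pair == (oth_c, eff_c):
            return Orientation.STRAND_FLIP_AS_IS
        if pair == (eff_c, oth_c):
            return Orientation.STRAND_FLIP_COMPLEMENTED
    raise AlleleAlignmentError(
        f"{rsid}: cannot orient alleles ref/alt={vcf_ref}/{vcf_alt} "
        f"to effect/other={effect_allele}/{other_allele}")


@dataclass
class GrsResult:
    """Per-subject scores: weighted sum, rescaled score, unweighted count."""

    scores: pd.DataFrame  # index subject_id; weighted_sum, rescaled, unweighted, [tertile]
    n_snps_used: int
    sum_beta: float

    @property
    def rescaled(self) -> pd.Series:
        return self.scores["rescaled"]

    @property
    def unweighted(self) -> pd.Series:
        return self.scores["unweighted"]

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index_label="subject_id")


def _filled_dosages(genotypes: GenotypeMatrix, panel: VariantPanel,
                    max_subject_missing: float = 0.1):
    """Mean-impute missing dosages with 2*EAF; drop heavily missing subjects."""
    d = genotypes.dosages.copy()
    subj_miss = np.isnan(d).mean(axis=1)
    keep = subj_miss <= max_subject_missing
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} subject(s) missing more than "
            f"{max_subject_missing:.0%} of panel SNPs", stacklevel=3)
    d = d[keep]
    fill = 2.0 * panel.eafs
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = fill[nan_c]
    ids = [s for s, k in zip(genotypes.subject_ids, keep) if k]
    return d, ids


def compute_weighted_grs(genotypes: GenotypeMatrix, panel: VariantPanel,
                         max_subject_missing: float = 0.1) -> GrsResult:
    """Weighted GRS: sum of beta x dosage, rescaled to risk-allele units.

    Missing dosages are imputed as 2 x EAF (the panel frequency) before
    summation; subjects missing more than ``max_subject_missing`` of the
    panel are dropped with a warning.  rescaled = weighted_sum x n / sum(beta).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    if panel.rsids != genotypes.rsids:
        genotypes = genotypes.subset_snps(panel.rsids)
    w = panel.betas
    if (w <= 0).any():
        raise ValueError("panel weights must be positive; call panel.normalize()")
    sum_beta = float(w.sum())
    if sum_beta == 0:
        raise ValueError("sum of weights is zero")
    d, ids = _filled_dosages(genotypes, panel, max_subject_missing)
    ws = d @ w
    unweighted = d.sum(axis=1)
    if np.all(w == w[0]):
        # constant weights: the rescaled score IS the allele count; bypass
        # the multiply-divide so the identity holds exactly
        rescaled = unweighted.copy()
    else:
        rescaled = ws * len(panel) / sum_beta
    scores = pd.DataFrame(
        {"weighted_sum": ws, "rescaled": rescaled, "unweighted": unweighted},
        index=pd.Index(ids, name="subject_id"))
    return GrsResult(scores, len(panel), sum_beta)


def compute_unweighted_grs(genotypes: GenotypeMatrix, panel: VariantPanel,
                           max_subject_missing: float = 0.1) -> GrsResult:
    """Unweighted GRS: plain risk-allele count (all weights 1)."""
    unit = VariantPanel(panel.table.assign(beta=1.0))
    return compute_weighted_grs(genotypes, unit, max_subject_missing)


def exclude_pleiotropic(panel: VariantPanel) -> VariantPanel:
    """Drop SNPs flagged as pleiotropic (associated with other metabolic traits)."""
    flagged = panel.table["pleiotropic"].astype(bool)
    if flagged.all():
        raise ValueError("every SNP is flagged pleiotropic; nothing left to score")
    n_removed = int(flagged.sum())
    log.info("excluding %d pleiotropic SNP(s); %d retained",
             n_removed, len(panel) - n_removed)
    return VariantPanel(panel.table.loc[~flagged].reset_index(drop=True))


def assign_tertiles(scores: pd.Series) -> tuple[pd.Series, tuple[int, int, int]]:
    """Rank-based tertiles (low/medium/high genetic risk).

    Subjects are ranked by score with ties broken by stable subject-id
    order; group sizes are n//3 each with remainder subjects allocated to
    the earlier (lower-score) groups, so n = 1414 splits 472/471/471.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    base, rem = divmod(n, 3)
    sizes = tuple(base + (1 if i < rem else 0) for i in range(3))
    order = scores.reset_index(drop=True).sort_values(kind="stable").index
    labels = np.empty(n, dtype=object)
    bounds = np.cumsum((0,) + sizes)
    for i, lab in enumerate(("low", "medium", "high")):
        labels[order[bounds[i]:bounds[i + 1]]] = lab
    out = pd.Series(labels, index=scores.index, name="tertile")
    return out, sizes  # type: ignore[return-value]
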