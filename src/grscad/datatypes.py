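"""Core in-memory containers shared across the pipeline.

The panel, genotype and phenotype containers are thin, validated wrappers
around pandas/numpy objects so that every stage (QC, scoring, modelling)
speaks the same language.  Phenotype tables are plain DataFrames with a
documented column dictionary (see :data:`PHENOTYPE_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantPanel",
    "GenotypeMatrix",
    "AssocResult",
    "PHENOTYPE_COLUMNS",
    "validate_phenotypes",
]

#: Column dictionary for phenotype tables.
PHENOTYPE_COLUMNS = {
    "subject_id": "unique subject identifier (string)",
    "age": "age at the index event, years",
    "male": "1 = male, 0 = female",
    "bmi": "body mass index at admission, kg/m^2",
    "current_smoker": "1 = smokes >1 cigarette/day or quit within 30 days",
    "hypertension": "1 = doctor-diagnosed or on antihypertensive therapy",
    "hypercholesterolemia": "1 = doctor-diagnosed or on lipid-lowering therapy",
    "t2d": "1 = self-reported doctor-diagnosed type 2 diabetes or antidiabetic medication",
    "vessels": "number of major coronary arteries with >=50% stenosis (1, 2 or 3)",
    "multi_vessel": "1 = two or more diseased vessels (derived from `vessels`)",
    "diagnosis": "index-event diagnosis: UA, STEMI or NSTEMI",
    "family_history_cad": "1 = first-degree relative with CAD",
    "prior_cvd": "1 = prior MI/revascularisation/stroke/heart failure/chronic angina/PVD",
    "underwent_angiography": "1 = coronary angiography performed (eligibility flag)",
    "significant_stenosis": "1 = at least one vessel with >=50% stenosis (eligibility flag)",
}

_REQUIRED_PHENO = ("subject_id", "age", "male", "bmi", "t2d")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table against the column dictionary.

    Returns the table (possibly with the derived ``multi_vessel`` column
    added) or raises ``ValueError``.
    """
    missing = [c for c in _REQUIRED_PHENO if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    if pheno["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in phenotype table")
    out = pheno.copy()
    if "vessels" in out.columns and "multi_vessel" not in out.columns:
        out["multi_vessel"] = (out["vessels"] >= 2).astype(int)
    return out


@dataclass
class VariantPanel:
    """Per-SNP metadata: identifiers, alleles, published weight, EAF, flags.

    ``table`` columns: rsid, chrom, pos, effect_allele, other_allele,
    beta (per-allele log-odds for T2D), eaf (effect-allele frequency),
    pleiotropic (bool).  After :meth:`normalize` every beta is positive,
    i.e. the effect allele is the risk allele.
    """

    table: pd.DataFrame

    REQUIRED = ("rsid", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "eaf", "pleiotropic")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel lacks columns: {missing}")
        if self.table["rsid"].duplicated().any():
            raise ValueError("duplicate rsids in panel")
        if (self.table["effect_allele"] == self.table["other_allele"]).any():
            raise ValueError("effect allele equals other allele for some SNP")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy(float)

    @property
    def eafs(self) -> np.ndarray:
        return self.table["eaf"].to_numpy(float)

    def normalize(self) -> "VariantPanel":
        """Orient every weight to the risk allele.

        Published negative betas are folded by swapping effect/other allele,
        negating beta and replacing the EAF by 1-EAF, so all stored weights
        are positive risk-allele weights.
        """
        t = self.table.copy()
        neg = t["beta"] < 0
        if neg.any():
            ea = t.loc[neg, "effect_allele"].copy()
            t.loc[neg, "effect_allele"] = t.loc[neg, "other_allele"]
            t.loc[neg, "other_allele"] = ea
            t.loc[neg, "beta"] = -t.loc[neg, "beta"]
            t.loc[neg, "eaf"] = 1.0 - t.loc[neg, "eaf"]
        return VariantPanel(t)

    def subset(self, rsids: Sequence[str]) -> "VariantPanel":
        keep = self.table["rsid"].isin(set(rsids))
        return VariantPanel(self.table.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele dosages with missingness and info scores.

    ``dosages`` is float with NaN marking missing calls; values lie in
    [0, 2].  ``info`` holds per-SNP imputation quality in [0, 1].
    """

    dosages: np.ndarray
    subject_ids: list[str]
    rsids: list[str]
    info: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        n, m = self.dosages.shape
        if len(self.subject_ids) != n or len(self.rsids) != m:
            raise ValueError("dosage dimensions disagree with id lists")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages outside [0, 2]")
        if self.info is None:
            self.info = np.ones(m)
        self.info = np.asarray(self.info, dtype=float)
        if self.info.shape != (m,):
            raise ValueError("info must be one value per SNP")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def hard_calls(self, max_distance: float = 0.1) -> np.ndarray | None:
        """Round dosages to integer genotypes.

        Returns the rounded int matrix (NaN preserved as -1) when every
        non-missing dosage is within ``max_distance`` of an integer,
        else None (fractional imputed dosages: hard-calling unsafe).
        """
        d = self.dosages
        ok = np.isnan(d) | (np.abs(d - np.round(d)) <= max_distance)
        if not ok.all():
            return None
        out = np.where(np.isnan(d), -1, np.round(d)).astype(int)
        return out

    def subset_snps(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.rsids.index(r) for r in rsids]
        return GenotypeMatrix(self.dosages[:, idx], list(self.subject_ids),
                              [self.rsids[i] for i in idx], self.info[idx])


@dataclass
class AssocResult:
    """One modelled term: log-odds, SE, OR with 95% CI, Wald p."""

    term: str
    beta: float
    se: float
    p: float
    model_tag: str
    n_used: int
    pooled: bool = False
    m_imputations: int = 0
    converged: bool = True
    separation: bool = False

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = float(np.exp(self.beta - 1.96 * self.se))
        hi = float(np.exp(self.beta + 1.96 * self.se))
        return lo, hi

    def as_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "term": self.term, "model": self.model_tag, "n": self.n_used,
            "beta": self.beta, "se": self.se, "OR": self.or_,
            "ci_low": lo, "ci_high": hi, "p": self.p,
            "pooled": self.pooled,
        }


def results_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Tabulate a collection of association results."""
    return pd.DataFrame([r.as_row() for r in results])
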