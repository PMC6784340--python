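"""End-to-end orchestration: simulate/load -> QC -> GRS -> models -> report.

A run writes a bundle of plain-text tables (baseline descriptives, nested
severity models, vessel-count model, spline curve, subgroup forest,
mediation triangle, sensitivity scores, power) plus a manifest recording
the configuration hash, seeds, stage-by-stage subject/SNP accounting and
the package version, so a re-run with the same manifest reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import results_frame, validate_phenotypes
from .grs import (assign_tertiles, compute_unweighted_grs, compute_weighted_grs,
                  exclude_pleiotropic)
from .impute import fit_pooled, mice_impute
from .io import (read_phenotypes, read_vcf, read_weights, write_phenotypes,
                 write_truth, write_vcf, write_weights)
from .mediation import MediationTriangle
from .models import (GrsSeverityModel, baseline_table, fit_rcs,
                     fit_vessel_count_model, interaction_and_strata)
from .power import PowerResult, closed_form_power, estimate_power
from .qc import QcThresholds, apply_variant_filters
from .simulate import SimConfig, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Either a SimConfig (self-contained run) or the three input paths."""

    sim: SimConfig | None = None
    vcf_path: str | None = None
    weights_path: str | None = None
    phenotypes_path: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    spline_knots: int = 4
    m_imputations: int = 9
    mice_cycles: int = 10
    power_reps: int = 2000
    power_or: float = 1.04
    power_alpha: float = 0.05
    seed: int = 0
    outdir: str = "grscad_run"

    def __post_init__(self) -> None:
        paths = (self.vcf_path, self.weights_path, self.phenotypes_path)
        if self.sim is None and any(p is None for p in paths):
            raise ValueError("provide either a SimConfig or all three input paths")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return the manifest dict (also written to disk).

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    outputs produced so far and the partial manifest are persisted.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "exclusions": [],
    }
    stage = "init"

    def _save_manifest():
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    try:
        stage = "input"
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cohort = generate_cohort(sim)
            panel, geno, pheno = cohort.panel, cohort.genotypes, cohort.phenotypes
            write_vcf(geno, panel, out / "genotypes.vcf")
            write_weights(panel, out / "weights.tsv")
            write_phenotypes(pheno, out / "phenotypes.csv")
            write_truth(cohort.truth, out / "truth.yaml")
        else:
            panel = read_weights(config.weights_path)
            geno = read_vcf(config.vcf_path, panel)
            pheno = read_phenotypes(config.phenotypes_path)
        pheno = validate_phenotypes(pheno)
        manifest["stages"]["input"] = {"subjects": len(pheno), "snps": len(panel)}

        stage = "eligibility"
        n0 = len(pheno)
        for flag, label in (("underwent_angiography", "no coronary angiography"),
                            ("significant_stenosis", "no stenosis >50%")):
            if flag in pheno.columns:
                drop = int((pheno[flag] == 0).sum())
                if drop:
                    keep = pheno[flag] != 0
                    pheno = pheno[keep].reset_index(drop=True)
                    keep_ids = set(pheno["subject_id"])
                    idx = [i for i, s in enumerate(geno.subject_ids)
                           if s in keep_ids]
                    geno = type(geno)(geno.dosages[idx],
                                      [geno.subject_ids[i] for i in idx],
                                      geno.rsids, geno.info)
                    manifest["exclusions"].append({"reason": label, "n": drop})
        manifest["stages"]["eligibility"] = {"in": n0, "out": len(pheno)}

        stage = "variant_qc"
        panel_qc, report = apply_variant_filters(panel, geno, config.qc)
        report.to_tsv(out / "qc_report.tsv")
        geno_qc = geno.subset_snps(panel_qc.rsids)
        manifest["stages"]["variant_qc"] = {
            "snps_in": len(panel), "snps_out": len(panel_qc),
            "dropped": report.table.loc[~report.table["pass"], "rsid"].tolist()}

        stage = "grs"
        grs = compute_weighted_grs(geno_qc, panel_qc)
        tert, sizes = assign_tertiles(grs.rescaled)
        grs.scores["tertile"] = tert.to_numpy()
        grs.to_csv(out / "scores.csv")
        manifest["stages"]["grs"] = {
            "snps_used": grs.n_snps_used, "subjects_scored": len(grs.scores),
            "tertile_sizes": list(sizes)}
        # align phenotypes to scored subjects
        pheno = pheno[pheno["subject_id"].isin(grs.scores.index)]
        pheno = pheno.reset_index(drop=True)

        has_missing = pheno.drop(columns=["vessels", "multi_vessel", "t2d"],
                                 errors="ignore").isna().any().any()

        stage = "baseline"
        baseline_table(pheno).to_csv(out / "table1.tsv", sep="\t", index=False)

        stage = "severity_models"
        model = GrsSeverityModel(pheno, grs)
        blocks = []
        for exposure in ("t2d_status", "per_sd", "per_allele", "tertile"):
            if has_missing:
                def _fn(tbl, e=exposure):
                    return GrsSeverityModel(tbl, grs).fit(e).results
                imp = mice_impute(pheno, m=config.m_imputations,
                                  cycles=config.mice_cycles, seed=config.seed)
                res = fit_pooled(imp, _fn)
            else:
                res = model.fit(exposure).results
            blocks.append(results_frame(res))
        pd.concat(blocks, ignore_index=True).to_csv(
            out / "table2.tsv", sep="\t", index=False)
        manifest["stages"]["severity_models"] = {
            "n": int(len(pheno)), "pooled": bool(has_missing)}

        # complete-case view for the stages that do not pool over imputations
        cc = pheno.dropna().reset_index(drop=True) if has_missing else pheno
        cc_scores = grs.rescaled.loc[cc["subject_id"]]

        stage = "vessel_count"
        results_frame(fit_vessel_count_model(cc, cc_scores)).to_csv(
            out / "table3.tsv", sep="\t", index=False)

        stage = "spline"
        sp = fit_rcs(cc, cc_scores, n_knots=config.spline_knots)
        sp.curve.assign(nonlinearity_p=sp.nonlinearity_p).to_csv(
            out / "spline_curve.tsv", sep="\t", index=False)
        manifest["stages"]["spline"] = {"nonlinearity_p": float(sp.nonlinearity_p),
                                        "knots": [float(k) for k in sp.knots]}

        stage = "subgroups"
        interaction_and_strata(cc, cc_scores).to_csv(
            out / "forest.tsv", sep="\t", index=False)

        stage = "mediation"
        tri = MediationTriangle(cc, cc_scores).fit()
        tri_tab = tri.or_table()
        tri_tab["p_compare"] = tri.p_compare
        tri_tab["attenuation"] = tri.attenuation
        tri_tab.to_csv(out / "triangle.tsv", sep="\t", index=False)
        manifest["stages"]["mediation"] = {
            "p_compare": float(tri.p_compare),
            "attenuation": float(tri.attenuation)}

        stage = "sensitivity"
        sens = []
        unw = compute_unweighted_grs(geno_qc, panel_qc)
        sens.append(results_frame(
            GrsSeverityModel(cc, unw.rescaled.loc[cc["subject_id"]])
            .fit("per_sd", ("model2",)).results).assign(score="unweighted"))
        panel_np = exclude_pleiotropic(panel_qc)
        grs_np = compute_weighted_grs(geno_qc.subset_snps(panel_np.rsids), panel_np)
        sens.append(results_frame(
            GrsSeverityModel(cc, grs_np.rescaled.loc[cc["subject_id"]])
            .fit("per_sd", ("model2",)).results)
            .assign(score=f"no_pleiotropic_{grs_np.n_snps_used}snp"))
        pd.concat(sens, ignore_index=True).to_csv(
            out / "sensitivity.tsv", sep="\t", index=False)

        stage = "power"
        case_frac = float(pheno["multi_vessel"].mean())
        sd = float(grs.rescaled.std(ddof=1))
        pr: PowerResult = estimate_power(
            n=len(pheno), case_fraction=case_frac, score_sd=sd,
            true_or=config.power_or, alpha=config.power_alpha,
            reps=config.power_reps, seed=config.seed)
        pd.DataFrame([{
            "n": pr.n, "case_fraction": pr.case_fraction, "score_sd": pr.score_sd,
            "true_or": pr.true_or, "alpha": pr.alpha, "reps": pr.reps,
            "power_hat": pr.power_hat, "mc_se": pr.mc_se,
            "closed_form": closed_form_power(pr.n, pr.case_fraction,
                                             pr.score_sd, pr.true_or, pr.alpha),
        }]).to_csv(out / "power.tsv", sep="\t", index=False)
        manifest["stages"]["power"] = {"power_hat": pr.power_hat}

        manifest["status"] = "ok"
        _save_manifest()
        return manifest
    except Exception as exc:  # persist partial manifest, then re-raise
        manifest["status"] = f"failed at {stage}"
        _save_manifest()
        raise PipelineError(stage, exc) from exc
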