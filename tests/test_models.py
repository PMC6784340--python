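"""Association models: closed-form checks, calibration, spline, subgroups."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from grscad.datatypes import GenotypeMatrix
from grscad.grs import assign_tertiles
from grscad.models import (GrsSeverityModel, _design, baseline_table,
                           fit_logistic, fit_rcs, fit_severity_models,
                           fit_vessel_count_model, interaction_and_strata,
                           rcs_basis, single_snp_scan, tertile_trend_test)
from grscad.simulate import SimConfig, generate_cohort

from oracles import cross_product_or, pearson_chi2_2x2


def _two_by_two_frame(a, b, c, d):
    """Rows: exposed cases (a), unexposed cases (b), exposed ctrls (c), unexposed ctrls (d)."""
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    return x, y


class TestClosedForm2x2:
    def test_logistic_reproduces_cross_product_or(self):
        """Crude T2D vs multi-vessel logistic on the printed counts.

        219 of 924 multi-vessel and 69 of 490 single-vessel patients have
        T2D; the ML logistic odds ratio must equal (219x421)/(705x69) and
        its SE the closed form sqrt(1/a+1/b+1/c+1/d), to 1e-6.
        """
        a, b, c, d = 219, 705, 69, 421
        x, y = _two_by_two_frame(a, b, c, d)
        res, conv, sep = fit_logistic(y, np.column_stack([np.ones_like(x), x]),
                                      ["const", "x"])
        or_oracle, se_oracle = cross_product_or(a, b, c, d)
        assert math.exp(res.params[1]) == pytest.approx(or_oracle, abs=1e-6)
        assert res.bse[1] == pytest.approx(se_oracle, abs=1e-6)
        assert or_oracle == pytest.approx(1.895, abs=0.001)

    def test_random_tables_match_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(20, 400, size=4)
            x, y = _two_by_two_frame(a, b, c, d)
            res, _, _ = fit_logistic(y, np.column_stack([np.ones_like(x), x]),
                                     ["const", "x"])
            or_o, se_o = cross_product_or(int(a), int(b), int(c), int(d))
            assert math.exp(res.params[1]) == pytest.approx(or_o, rel=1e-6)
            assert res.bse[1] == pytest.approx(se_o, rel=1e-6)


class TestBaselineTable:
    def test_t2d_percentage_formatting(self, study_cohort):
        tab = baseline_table(study_cohort.phenotypes)
        row = tab[tab["variable"] == "t2d"].iloc[0]
        n_t2d = int(study_cohort.phenotypes["t2d"].sum())
        pct = 100 * n_t2d / len(study_cohort.phenotypes)
        assert row["total"] == f"{n_t2d} ({pct:.1f})"

    def test_chi2_matches_hand_computed_pearson(self):
        # 2x2 of T2D by severity group with the study's marginal counts
        ph = pd.DataFrame({
            "t2d": np.r_[np.ones(69), np.zeros(421), np.ones(219), np.zeros(705)],
            "multi_vessel": np.r_[np.zeros(490), np.ones(924)],
            "age": 60.0, "bmi": 24.7, "male": 1,
        })
        tab = baseline_table(ph, continuous=())
        row = tab[tab["variable"] == "t2d"].iloc[0]
        chi2 = pearson_chi2_2x2(69, 421, 219, 705)
        assert row["p"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)

    def test_identical_groups_give_p_one(self):
        half = pd.DataFrame({"age": np.tile([50.0, 60, 70, 80], 25),
                             "bmi": 24.0, "male": np.tile([0, 1], 50),
                             "t2d": np.tile([0, 1], 50)})
        ph = pd.concat([half.assign(multi_vessel=0), half.assign(multi_vessel=1)],
                       ignore_index=True)
        tab = baseline_table(ph)
        assert (tab["p"] > 0.99).all()

    def test_empty_stratum_rejected(self, study_cohort):
        ph = study_cohort.phenotypes.copy()
        ph["multi_vessel"] = 1
        with pytest.raises(ValueError):
            baseline_table(ph)


class TestSeverityModels:
    def test_per_sd_is_rescaled_per_allele(self, clean_cohort, clean_grs):
        """Per-SD and per-allele fits are the same model on different scales."""
        pa = fit_severity_models(clean_cohort.phenotypes, clean_grs,
                                 "per_allele", ("model2",))[0]
        ps = fit_severity_models(clean_cohort.phenotypes, clean_grs,
                                 "per_sd", ("model2",))[0]
        sd = clean_grs.rescaled.std(ddof=1)
        assert ps.beta == pytest.approx(pa.beta * sd, rel=1e-9)
        assert ps.p == pytest.approx(pa.p, rel=1e-6)

    def test_null_exposure_recovered_near_one(self):
        cfg = SimConfig(n_subjects=50_000, seed=21, beta_G=0.0, beta_D=0.0,
                        beta_direct=0.0)
        c = generate_cohort(cfg)
        from grscad.grs import compute_weighted_grs
        grs = compute_weighted_grs(c.genotypes, c.panel)
        r = fit_severity_models(c.phenotypes, grs, "per_allele", ("model1",))[0]
        assert 0.98 <= r.or_ <= 1.02

    def test_t2d_status_skips_model3(self, clean_cohort, clean_grs):
        res = fit_severity_models(clean_cohort.phenotypes, clean_grs, "t2d_status")
        assert [r.model_tag for r in res] == ["model1", "model2"]

    def test_tertile_contrasts_and_sizes(self, clean_cohort, clean_grs):
        fitted = GrsSeverityModel(clean_cohort.phenotypes, clean_grs).fit(
            "tertile", ("model2",))
        assert [r.term for r in fitted.results] == ["tertile_medium", "tertile_high"]
        assert fitted.tertile_sizes == (667, 667, 666)
        assert fitted.trend is not None

    def test_unknown_exposure_rejected(self, clean_cohort, clean_grs):
        with pytest.raises(ValueError):
            GrsSeverityModel(clean_cohort.phenotypes, clean_grs).fit("per_quintile")


class TestTrendTest:
    def test_monotone_effect_detected(self, big_cohort, big_grs):
        r = tertile_trend_test(big_cohort.phenotypes, big_grs)
        assert r.p < 1e-3
        assert r.beta > 0

    def test_reversed_index_negates_beta(self, clean_cohort, clean_grs):
        r = tertile_trend_test(clean_cohort.phenotypes, clean_grs)
        ph = clean_cohort.phenotypes
        labels, _ = assign_tertiles(pd.Series(
            clean_grs.rescaled.to_numpy(), index=ph["subject_id"].to_numpy()))
        idx = np.where(labels == "low", 2.0, np.where(labels == "medium", 1.0, 0.0))
        X, names = _design(ph, ("age", "male", "bmi", "current_smoker",
                                "hypertension", "hypercholesterolemia"),
                           {"tertile_index": idx})
        res, _, _ = fit_logistic(ph["multi_vessel"].to_numpy(float), X, names)
        assert res.params[names.index("tertile_index")] == pytest.approx(-r.beta, rel=1e-6)
        assert res.pvalues[names.index("tertile_index")] == pytest.approx(r.p, rel=1e-6)


class TestVesselCountModel:
    def test_two_categories_collapse_to_binary_logit(self):
        """With only 1- and 2-vessel subjects the multinomial equals the logistic."""
        cfg = SimConfig(n_subjects=3000, seed=30)
        c = generate_cohort(cfg)
        from grscad.grs import compute_weighted_grs
        grs = compute_weighted_grs(c.genotypes, c.panel)
        ph = c.phenotypes.copy()
        ph["vessels"] = ph["vessels"].clip(upper=2)
        ph["multi_vessel"] = (ph["vessels"] >= 2).astype(int)
        mn = fit_vessel_count_model(ph, grs, models=("model1",))
        bi = GrsSeverityModel(ph, grs.rescaled / grs.rescaled.std(ddof=1)).fit(
            "per_allele", ("model1",)).results[0]
        assert len(mn) == 1
        assert mn[0].beta == pytest.approx(bi.beta, abs=1e-6)

    def test_single_category_rejected(self, clean_cohort, clean_grs):
        ph = clean_cohort.phenotypes.copy()
        ph["vessels"] = 2
        with pytest.raises(ValueError):
            fit_vessel_count_model(ph, clean_grs)


class TestSpline:
    def test_basis_dimension_and_linearity_beyond_boundaries(self):
        x = np.linspace(0, 10, 200)
        knots = np.array([2.0, 4, 6, 8])
        B = rcs_basis(x, knots)
        assert B.shape == (200, 3)  # knots - 1 df
        # beyond the boundary knots every column is affine in x
        right = x > 8.5
        for j in range(B.shape[1]):
            slope = np.diff(B[right, j]) / np.diff(x[right])
            assert np.allclose(slope, slope[0], atol=1e-8)

    def test_reference_or_is_one(self, clean_cohort, clean_grs):
        sp = fit_rcs(clean_cohort.phenotypes, clean_grs)
        # interpolate the curve at the reference score
        or_ref = np.interp(sp.reference, sp.curve["score"], sp.curve["OR"])
        assert or_ref == pytest.approx(1.0, abs=5e-3)

    def test_quadratic_signal_detected(self):
        """A strongly curved dose-response yields nonlinearity p < 0.001."""
        rng = np.random.default_rng(40)
        n = 20_000
        score = rng.normal(48, 4, n)
        z = (score - 48) / 4
        eta = 0.2 * z + 0.25 * z ** 2 - 0.6
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ph = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.normal(60, 8, n), "male": rng.integers(0, 2, n),
            "bmi": rng.normal(24.7, 3, n), "current_smoker": rng.integers(0, 2, n),
            "hypertension": rng.integers(0, 2, n),
            "hypercholesterolemia": rng.integers(0, 2, n),
            "t2d": rng.integers(0, 2, n), "multi_vessel": y})
        sp = fit_rcs(ph, pd.Series(score), n_knots=4)
        assert sp.nonlinearity_p < 1e-3

    def test_invalid_knot_count(self, clean_cohort, clean_grs):
        with pytest.raises(ValueError):
            fit_rcs(clean_cohort.phenotypes, clean_grs, n_knots=7)

    def test_coincident_knots_rejected(self, clean_cohort):
        const = pd.Series(np.ones(len(clean_cohort.phenotypes)))
        with pytest.raises(ValueError):
            fit_rcs(clean_cohort.phenotypes, const)


class TestInteractionStrata:
    def test_forest_layout_and_strata_counts(self, clean_cohort, clean_grs):
        tab = interaction_and_strata(clean_cohort.phenotypes, clean_grs)
        assert {"factor", "level", "n", "OR", "ci_low", "ci_high", "p",
                "p_interaction"} <= set(tab.columns)
        for _, grp in tab.groupby("factor"):
            assert grp["n"].sum() == len(clean_cohort.phenotypes)
            assert grp["p_interaction"].nunique() == 1

    def test_deviance_decomposition(self):
        """Stratifying on a factor outside the model splits the deviance.

        Fitting separately within the two strata of a covariate that is not
        in the model must give the same total deviance as one pooled fit in
        which every term interacts with the stratifier.
        """
        rng = np.random.default_rng(50)
        n = 2000
        x = rng.normal(size=n)
        age = rng.normal(60, 8, n)
        f = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.3 * x + 0.02 * (age - 60)
                                               + 0.4 * f * x)))).astype(float)
        dev = 0.0
        for lvl in (0, 1):
            m = f == lvl
            X = np.column_stack([np.ones(m.sum()), x[m], age[m]])
            res = sm.Logit(y[m], X).fit(disp=0)
            dev += -2 * res.llf
        Xp = np.column_stack([np.ones(n), x, age, f, x * f, age * f])
        pooled = sm.Logit(y, Xp).fit(disp=0)
        assert dev == pytest.approx(-2 * pooled.llf, abs=1e-6)

    def test_strong_interaction_detected(self):
        """Effect confined to one stratum: small interaction p, ordered ORs."""
        rng = np.random.default_rng(51)
        n = 20_000
        score = rng.normal(0, 1, n)
        htn = rng.integers(0, 2, n)
        eta = -0.3 + 0.35 * score * htn
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ph = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.normal(60, 8, n), "male": rng.integers(0, 2, n),
            "bmi": 24.7, "current_smoker": 0, "hypertension": htn,
            "hypercholesterolemia": 0, "t2d": 0, "multi_vessel": y})
        tab = interaction_and_strata(
            ph, pd.Series(score),
            subgroups=[("hypertension", ph["hypertension"] == 1, ())])
        assert tab["p_interaction"].iloc[0] < 1e-3
        in_or = tab.loc[tab["level"] == 1, "OR"].iloc[0]
        out_or = tab.loc[tab["level"] == 0, "OR"].iloc[0]
        assert in_or > out_or

    def test_degenerate_stratum_skipped(self, clean_cohort, clean_grs):
        ph = clean_cohort.phenotypes.copy()
        flag = pd.Series(False, index=ph.index)
        flag.iloc[:3] = True
        ph.loc[flag.to_numpy(), "multi_vessel"] = 1  # degenerate tiny stratum
        tab = interaction_and_strata(ph, clean_grs,
                                     subgroups=[("tiny", flag, ())])
        assert np.isnan(tab.loc[tab["level"] == 1, "OR"].iloc[0])


class TestSingleSnpScan:
    def test_null_panel_rejection_rate_near_alpha(self, clean_cohort):
        """Without direct SNP effects, ~5% of SNPs reach p < 0.05."""
        cfg = SimConfig(n_subjects=4000, seed=33, beta_G=0.0, beta_D=0.0,
                        beta_direct=0.0)
        c = generate_cohort(cfg)
        tab = single_snp_scan(c.genotypes, c.panel, c.phenotypes)
        frac = (tab["p"] < 0.05).mean()
        assert frac <= 0.2  # 42 SNPs: expect ~2 hits, allow binomial noise

    def test_injected_snp_effect_recovered(self):
        rng = np.random.default_rng(60)
        n = 20_000
        cfg = SimConfig(n_subjects=n, seed=34, beta_G=0.0, beta_D=0.0,
                        beta_direct=0.0, n_snps=5)
        c = generate_cohort(cfg)
        ph = c.phenotypes.copy()
        d = c.genotypes.dosages[:, 2]
        true_beta = 0.25
        eta = -0.2 + true_beta * (d - d.mean())
        ph["multi_vessel"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        tab = single_snp_scan(c.genotypes, c.panel, ph)
        hit = tab.set_index("rsid").loc[c.panel.rsids[2]]
        assert hit["p"] < 1e-6
        assert math.log(hit["OR"]) == pytest.approx(true_beta, rel=0.10)

    def test_monomorphic_snp_skipped(self, clean_cohort):
        geno = clean_cohort.genotypes
        d = geno.dosages.copy()
        d[:, 0] = 2.0
        g2 = GenotypeMatrix(d, geno.subject_ids, geno.rsids, geno.info)
        tab = single_snp_scan(g2, clean_cohort.panel, clean_cohort.phenotypes)
        assert tab.iloc[0]["note"] == "monomorphic"
        assert np.isnan(tab.iloc[0]["OR"])

    def test_empty_panel_rejected(self, clean_cohort):
        with pytest.raises(ValueError):
            single_snp_scan(clean_cohort.genotypes,
                            clean_cohort.panel.subset([]),
                            clean_cohort.phenotypes)
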