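"""Logistic and CMH association against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import t2drep as t
from t2drep.association import MonomorphicError, cmh_test, fit_logistic_additive

from conftest import SEED


def binary_cohort(a, b, c, d):
    """Cohort with binary dosage: cases a exposed / b unexposed,
    controls c exposed / d unexposed."""
    status = [1] * (a + b) + [0] * (c + d)
    dosage = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
    n = len(status)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "status": status,
            "age": 50.0,
            "sex": "F",
            "stratum": "Sinhalese",
            "gada_positive": 0,
            "early_insulin": 0,
            "mitochondrial": 0,
            "g": dosage,
        }
    )


class TestLogistic:
    def test_matches_2x2_closed_form_to_6_sig_figs(self):
        """With a single binary predictor and no covariates the ML logistic
        fit equals the analytic cross-product OR ad/bc with the Woolf CI
        and Wald p."""
        a, b, c, d = 37, 63, 25, 75
        fit = fit_logistic_additive(binary_cohort(a, b, c, d), "g", covariates=())
        or_oracle = a * d / (b * c)
        se_oracle = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        assert fit.odds_ratio == pytest.approx(or_oracle, rel=1e-7)
        assert fit.se == pytest.approx(se_oracle, rel=1e-7)
        assert fit.ci_lo == pytest.approx(or_oracle * np.exp(-z * se_oracle), rel=1e-6)
        assert fit.ci_hi == pytest.approx(or_oracle * np.exp(z * se_oracle), rel=1e-6)
        p_oracle = 2 * stats.norm.sf(abs(np.log(or_oracle)) / se_oracle)
        assert fit.p_value == pytest.approx(p_oracle, rel=1e-6)

    def test_allele_flip_inverts_or_and_preserves_p(self, table1_cohort):
        """Counting the other allele (dosage -> 2 - dosage) inverts the OR
        and leaves the Wald p-value unchanged."""
        coh = table1_cohort
        snp = "rs7903146"
        fit = fit_logistic_additive(coh, snp)
        flipped = coh.copy()
        flipped[snp] = 2.0 - flipped[snp]
        fit_f = fit_logistic_additive(flipped, snp)
        assert abs(np.log(fit.odds_ratio * fit_f.odds_ratio)) < 1e-8
        assert abs(fit.p_value - fit_f.p_value) < 1e-10

    def test_null_type_one_error_calibrated(self):
        """True OR = 1: the Wald test rejects at the nominal 5% rate
        (within 0.05 +/- 0.02 over 1000 replicates)."""
        rej = 0
        reps = 1000
        for rep in range(reps):
            cfg = t.SimulationConfig(
                n_cases=150, n_controls=250, seed=SEED + 7000 + rep,
                snps=[t.SimSnp("g", 0.3, 1.0)],
            )
            coh = t.simulate_cohort(cfg)
            fit = fit_logistic_additive(coh, "g", covariates=())
            rej += fit.p_value <= 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_recovers_simulation_truth_loosely(self):
        """Quick recovery check at study scale (the full 200-replicate
        version lives in the acceptance suite)."""
        betas = []
        for rep in range(40):
            cfg = t.SimulationConfig(
                n_cases=830, n_controls=1497, seed=SEED + 9000 + rep,
                snps=[t.SimSnp("g", 0.34, 1.38)],
            )
            fit = fit_logistic_additive(t.simulate_cohort(cfg), "g")
            betas.append(fit.beta)
        assert np.exp(np.mean(betas)) == pytest.approx(1.38, abs=0.07)

    def test_monomorphic_raises(self):
        coh = binary_cohort(5, 0, 5, 0)
        with pytest.raises(MonomorphicError):
            fit_logistic_additive(coh, "g", covariates=())

    def test_all_one_class_raises(self):
        coh = binary_cohort(5, 5, 0, 0)
        with pytest.raises(ValueError, match="case and one control"):
            fit_logistic_additive(coh, "g", covariates=())

    def test_collinear_covariate_dropped(self):
        """Sex is dropped (and recorded) when it is collinear, e.g. in a
        single-sex subset."""
        coh = binary_cohort(30, 20, 20, 30)  # all female
        fit = fit_logistic_additive(coh, "g", covariates=("sex",))
        assert fit.dropped_covariates == ("sex",)
        assert np.isfinite(fit.odds_ratio)


class TestOrientation:
    def ann(self, risk_study="A", chrom="1"):
        return pd.Series(
            {
                "snp_id": "g", "chromosome": chrom, "effect_allele": "A",
                "other_allele": "G", "risk_allele_study": risk_study,
                "risk_allele_reference": risk_study,
            }
        )

    def test_risk_equals_effect_is_identity(self):
        d = pd.Series([0.0, 1.0, 2.0, np.nan])
        out = t.orient_to_risk_allele(d, self.ann("A"))
        pd.testing.assert_series_equal(out, d)

    def test_complement_on_autosome(self):
        d = pd.Series([0.0, 1.0, 2.0, np.nan])
        out = t.orient_to_risk_allele(d, self.ann("G"))
        assert out.tolist()[:3] == [2.0, 1.0, 0.0]
        assert np.isnan(out.iloc[3])

    def test_male_x_complement_is_hemizygous(self):
        d = pd.Series([0.0, 1.0, 0.0, 2.0])
        sex = pd.Series(["M", "M", "F", "F"])
        out = t.orient_to_risk_allele(d, self.ann("G", chrom="X"), sex=sex)
        assert out.tolist() == [1.0, 0.0, 2.0, 0.0]

    def test_unknown_risk_allele_fails(self):
        ann = self.ann("A")
        ann["risk_allele_study"] = "T"
        with pytest.raises(ValueError, match="not one of"):
            t.orient_to_risk_allele(pd.Series([1.0]), ann)


class TestCmh:
    def test_single_stratum_equals_allelic_2x2(self):
        """One stratum degenerates to the ordinary allelic odds ratio."""
        coh = binary_cohort(40, 60, 30, 70)
        fit = cmh_test(coh, "g")
        # allele counts: each diploid sample contributes 2 alleles
        a, b = 40.0, 2 * 100 - 40.0
        c, d = 30.0, 2 * 100 - 30.0
        assert fit.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-12)
        assert fit.n_strata_used == 1

    def test_duplicate_strata_equal_single_table(self):
        """Two identical strata pool to the single-table OR by the
        Mantel-Haenszel formula sum(ad/n)/sum(bc/n)."""
        coh1 = binary_cohort(40, 60, 30, 70)
        coh2 = coh1.copy()
        coh2["stratum"] = "Tamil"
        coh2["sample_id"] = coh2["sample_id"] + "_b"
        both = pd.concat([coh1, coh2], ignore_index=True)
        single = cmh_test(coh1, "g")
        pooled = cmh_test(both, "g")
        assert pooled.odds_ratio == pytest.approx(single.odds_ratio, rel=1e-12)
        assert pooled.n_strata_used == 2
        # hand MH formula on the allelic tables
        a, b, c, d = 40.0, 160.0, 30.0, 170.0
        n = a + b + c + d
        mh = (2 * (a * d / n)) / (2 * (b * c / n))
        assert pooled.odds_ratio == pytest.approx(mh, rel=1e-12)

    def test_stratification_removes_designed_confounding(self):
        """A SNP null within strata but confounded across them (the stratum
        shifts both RAF and disease rate) shows a crude OR away from 1
        while the CMH OR stays near 1."""
        cfg = t.SimulationConfig(
            n_cases=1200, n_controls=1800, seed=SEED,
            snps=[t.SimSnp("g", 0.4, 1.0)],
            strata=[
                t.Stratum("A", 0.5, raf_offset=+0.2, disease_log_or=+1.0),
                t.Stratum("B", 0.5, raf_offset=-0.2),
            ],
        )
        coh = t.simulate_cohort(cfg)
        crude = coh.copy()
        crude["stratum"] = "pooled"
        fit_crude = cmh_test(crude, "g")
        fit_cmh = cmh_test(coh, "g")
        assert fit_crude.odds_ratio > 1.10
        assert abs(np.log(fit_cmh.odds_ratio)) < abs(np.log(fit_crude.odds_ratio)) / 3
        assert fit_cmh.ci_lo < 1.0 < fit_cmh.ci_hi

    def test_zero_margin_stratum_skipped_with_note(self):
        coh = binary_cohort(40, 60, 30, 70)
        empty = binary_cohort(0, 10, 0, 10)  # no risk alleles at all
        empty["stratum"] = "Tamil"
        empty["sample_id"] = empty["sample_id"] + "_b"
        both = pd.concat([coh, empty], ignore_index=True)
        fit = cmh_test(both, "g")
        assert fit.n_strata_used == 1
        assert any("Tamil" in note for note in fit.notes)

    def test_all_degenerate_raises(self):
        coh = binary_cohort(0, 10, 0, 10)
        with pytest.raises(ValueError, match="zero margin"):
            cmh_test(coh, "g")

    def test_dosage_logistic_and_allelic_cmh_agree_under_hwe(self, table1_cohort):
        """The genotype-dosage logistic model and the allele-count CMH
        estimate the same per-allele OR to within 5% when HWE holds."""
        for snp in ("rs7903146", "rs13266634", "rs10811661", "rs340874"):
            fit_log = fit_logistic_additive(table1_cohort, snp, covariates=())
            pooled = table1_cohort.copy()
            pooled["stratum"] = "all"
            fit_mh = cmh_test(pooled, snp)
            assert fit_log.odds_ratio == pytest.approx(fit_mh.odds_ratio, rel=0.05)


class TestPanel:
    def test_schema_and_annotation_order(self, table1_cohort, table1):
        res = t.run_association_panel(table1_cohort, table1)
        assert res["snp_id"].tolist() == table1["snp_id"].tolist()
        for col in ("raf", "or_adjusted", "p_adjusted", "or_cmh", "p_cmh"):
            assert res[col].notna().all()
        assert (res["note"] == "").all()
        assert res["n_used"].between(1, len(table1_cohort)).all()

    def test_adjusted_and_cmh_ors_highly_correlated(self, table1_cohort, table1):
        """Without stratum confounding the two analyses estimate the same
        quantity: Pearson r of the OR vectors above 0.95 at study scale."""
        res = t.run_association_panel(table1_cohort, table1)
        r = np.corrcoef(res["or_adjusted"], res["or_cmh"])[0, 1]
        assert r > 0.95

    def test_panel_oriented_to_risk_allele(self, table1_cohort, table1):
        """Simulation truth has every OR on the risk-allele scale; fitted
        RAFs must match the design RAFs closely."""
        res = t.run_association_panel(table1_cohort, table1).set_index("snp_id")
        for _, ann in table1.iterrows():
            assert res.loc[ann["snp_id"], "raf"] == pytest.approx(
                ann["raf_study"], abs=0.04
            )

    def test_x_snp_male_alleles_counted_once(self):
        """Hemizygous males contribute one allele each to the CMH table."""
        coh = binary_cohort(10, 10, 10, 10)
        coh["sex"] = ["M"] * 20 + ["F"] * 20
        fit = cmh_test(coh, "g", x_snps=["g"])
        assert fit.n_used == 40
        # cases (all male): 10 risk / 10 other alleles; controls (female,
        # diploid): 10 risk / 30 other -> OR = (10*30)/(10*10) = 3
        assert fit.odds_ratio == pytest.approx(3.0, rel=1e-12)
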