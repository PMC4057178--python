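"""Exclusion bookkeeping, call-rate filtering, and HWE testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import t2drep as t
from t2drep.qc import (
    CallRateFilter,
    CaseDefinitionFilter,
    HWEFilter,
    QcConfig,
    hwe_exact_test,
    hwe_test,
)

from conftest import SEED, make_annotations


def toy_cohort(n_cases, n_controls, n_snps=2, flags=None):
    n = n_cases + n_controls
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "status": [1] * n_cases + [0] * n_controls,
            "age": 50.0,
            "sex": "F",
            "stratum": "Sinhalese",
            "gada_positive": 0.0,
            "early_insulin": 0,
            "mitochondrial": 0,
        }
    )
    for j in range(n_snps):
        df[f"g{j}"] = 1.0
    if flags:
        for col, idx, val in flags:
            df.loc[list(idx), col] = val
    return df


class TestCaseDefinition:
    def test_study_arithmetic_965_to_878(self):
        """29 missing-GADA + 48 early-insulin + 10 mitochondrial exclusions
        from 965 cases leave 878."""
        coh = toy_cohort(
            965, 100,
            flags=[
                ("gada_positive", range(0, 29), np.nan),
                ("early_insulin", range(29, 77), 1),
                ("mitochondrial", range(77, 87), 1),
            ],
        )
        kept, report = t.apply_case_definition(coh)
        assert report.counts == {
            "missing_gada": 29, "gada_positive": 0,
            "early_insulin": 48, "mitochondrial": 10,
        }
        assert (kept["status"] == 1).sum() == 878
        assert (kept["status"] == 0).sum() == 100
        report.check()

    def test_all_flags_clear_is_identity(self):
        coh = toy_cohort(20, 30)
        kept, report = t.apply_case_definition(coh)
        pd.testing.assert_frame_equal(kept, coh)
        assert report.n_excluded == 0

    def test_overlapping_flags_counted_once_in_rule_order(self):
        """A case with both early-insulin and mitochondrial flags is counted
        under the first matching rule only; controls are never touched."""
        coh = toy_cohort(3, 2)
        coh.loc[0, ["early_insulin", "mitochondrial"]] = 1
        coh.loc[1, "gada_positive"] = np.nan
        coh.loc[1, "early_insulin"] = 1
        coh.loc[3, ["early_insulin", "mitochondrial"]] = 1  # a control
        kept, report = t.apply_case_definition(coh)
        assert report.counts == {
            "missing_gada": 1, "gada_positive": 0,
            "early_insulin": 1, "mitochondrial": 0,
        }
        assert len(kept) == 3
        assert coh.loc[3, "sample_id"] in set(kept["sample_id"])

    def test_idempotent(self):
        coh = toy_cohort(10, 5, flags=[("early_insulin", [0, 1], 1)])
        once, _ = t.apply_case_definition(coh)
        twice, rep = t.apply_case_definition(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep.n_excluded == 0


class TestCallRate:
    def test_hand_fractions_at_threshold(self):
        """28/36 calls (0.778) is removed at 0.80; 29/36 (0.806) is kept."""
        coh = toy_cohort(2, 0, n_snps=36)
        coh.iloc[0, coh.columns.get_loc("g0") : coh.columns.get_loc("g0") + 8] = np.nan
        coh.iloc[1, coh.columns.get_loc("g0") : coh.columns.get_loc("g0") + 7] = np.nan
        kept, report = t.filter_sample_call_rate(coh)
        assert report.counts["low_call_rate"] == 1
        assert kept["sample_id"].tolist() == ["S1"]
        rates = report.details["call_rates"]
        assert rates["S0"] == pytest.approx(28 / 36)
        assert rates["S1"] == pytest.approx(29 / 36)

    def test_exact_boundary_kept(self):
        """Strict inequality: a call rate exactly at the threshold stays."""
        coh = toy_cohort(1, 1, n_snps=10)
        coh.loc[0, ["g0", "g1"]] = np.nan  # exactly 0.8
        kept, _ = t.filter_sample_call_rate(coh, QcConfig(sample_call_rate_min=0.8))
        assert len(kept) == 2

    def test_negligible_threshold_is_identity(self, small_cohort):
        kept, report = t.filter_sample_call_rate(
            small_cohort, QcConfig(sample_call_rate_min=1e-9)
        )
        pd.testing.assert_frame_equal(kept, small_cohort)
        assert report.n_excluded == 0

    def test_idempotent_and_bookkeeping(self, small_cohort):
        once, r1 = t.filter_sample_call_rate(small_cohort)
        twice, r2 = t.filter_sample_call_rate(once)
        pd.testing.assert_frame_equal(once, twice)
        r1.check()
        assert r1.n_input == len(small_cohort)
        assert r1.n_remaining == len(once)


class TestHweTest:
    def test_perfect_hwe_counts(self):
        res = hwe_test(25, 50, 25)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_complete_het_deficit(self):
        """(50, 0, 50) has expectation (25, 50, 25), chi-square 100."""
        res = hwe_test(50, 0, 50)
        assert res.chi_square == pytest.approx(100.0)
        assert res.p_value < 1e-20

    def test_monomorphic_flagged(self):
        res = hwe_test(120, 0, 0)
        assert res == (0.0, 1.0, True)

    @pytest.mark.parametrize("counts", [(30, 40, 30), (81, 18, 1), (5, 90, 5)])
    def test_matches_scipy_chisquare_oracle(self, counts):
        n = sum(counts)
        p = (2 * counts[2] + counts[1]) / (2 * n)
        expected = [n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2]
        chi2, pval = stats.chisquare(counts, expected, ddof=1)
        res = hwe_test(*counts)
        assert res.chi_square == pytest.approx(chi2)
        assert res.p_value == pytest.approx(pval)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestHweExact:
    @pytest.mark.parametrize("counts", [(7, 2, 1), (2, 6, 2), (10, 1, 4)])
    def test_matches_enumeration_oracle(self, counts):
        """Exact-test p equals brute-force enumeration of all heterozygote
        configurations with the same allele counts, in rational arithmetic."""
        from fractions import Fraction
        from math import comb, factorial

        n = sum(counts)
        n_alt = 2 * counts[2] + counts[1]
        n_minor = min(n_alt, 2 * n - n_alt)
        probs = {}
        for h in range(n_minor % 2, n_minor + 1, 2):
            hom_min = (n_minor - h) // 2
            hom_maj = n - h - hom_min
            probs[h] = Fraction(
                2**h * factorial(n) * factorial(n_minor) * factorial(2 * n - n_minor),
                factorial(hom_min) * factorial(h) * factorial(hom_maj) * factorial(2 * n),
            )
        p_obs = probs[counts[1]]
        expected = float(sum(v for v in probs.values() if v <= p_obs))
        assert hwe_exact_test(*counts).p_value == pytest.approx(expected, rel=1e-9)


@pytest.fixture(scope="module")
def violated_panel():
    snps = [t.SimSnp(f"g{i}", 0.2 + 0.015 * i, 1.0) for i in range(36)]
    snps.append(t.SimSnp("g_bad", 0.4, 1.0, hwe_violation_factor=0.5))
    cfg = t.SimulationConfig(n_cases=400, n_controls=1500, seed=SEED, snps=snps)
    return t.simulate_cohort(cfg), make_annotations(cfg)


class TestFilterHwe:
    def test_injected_violation_removed_36_remain(self, violated_panel):
        coh, ann = violated_panel
        kept, kept_ann, report = t.filter_hwe(coh, ann)
        assert report.excluded["hwe_violation"] == ["g_bad"]
        assert report.n_remaining == 36
        assert "g_bad" not in kept.columns
        assert "g_bad" not in set(kept_ann["snp_id"])

    def test_all_in_hwe_is_identity(self, small_cohort, small_annotations):
        kept, kept_ann, report = t.filter_hwe(small_cohort, small_annotations)
        pd.testing.assert_frame_equal(kept, small_cohort)
        assert report.n_excluded == 0

    def test_alpha_one_removes_everything(self, violated_panel):
        coh, ann = violated_panel
        kept, kept_ann, report = t.filter_hwe(coh, ann, QcConfig(hwe_alpha=1.0))
        assert report.n_remaining == 0
        assert len(kept_ann) == 0

    def test_x_snp_tested_in_females_only(self, small_cohort, small_annotations):
        _, _, report = t.filter_hwe(small_cohort, small_annotations)
        table = report.details["hwe"].set_index("snp_id")
        assert table.loc["rs_x", "population"] == "controls:females"
        n_control_females = len(
            small_cohort[(small_cohort["status"] == 0) & (small_cohort["sex"] == "F")]
        )
        assert table.loc["rs_x", "n"] <= n_control_females

    def test_no_controls_is_an_error(self, small_cohort, small_annotations):
        cases_only = small_cohort[small_cohort["status"] == 1]
        with pytest.raises(ValueError, match="no controls"):
            t.filter_hwe(cases_only, small_annotations)


class TestSklearnFacade:
    def test_filters_chain_and_report(self, small_cohort, small_annotations):
        pipe_out = CaseDefinitionFilter().fit_transform(small_cohort)
        cr = CallRateFilter(min_call_rate=0.8)
        pipe_out = cr.fit_transform(pipe_out)
        hw = HWEFilter(annotations=small_annotations)
        pipe_out = hw.fit_transform(pipe_out)
        assert cr.report_.n_remaining == len(pipe_out)
        assert hw.report_.n_input == len(small_annotations)
        assert cr.get_params()["min_call_rate"] == 0.8

    def test_hwe_filter_requires_annotations(self, small_cohort):
        with pytest.raises(ValueError, match="annotation"):
            HWEFilter().fit_transform(small_cohort)
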