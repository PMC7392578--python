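"""Cohort statistics: accounting, chi-square, mixed-model trajectories."""

import numpy as np
import pandas as pd
import pytest

import foveometrics as fm
from foveometrics.errors import (
    AccountingError,
    CohortValidationError,
    ParameterError,
    UndefinedTestError,
)


class TestAccounting:
    def test_percentages_use_correct_denominators(self):
        acc = fm.cohort_accounting(fm.CohortCounts(
            recruited=200, unanalyzable=50, cystic=30, analyzed=120,
            never_rop=60, always_rop=30, mixed_rop=30))
        by = acc.set_index("group")
        assert by.loc["unanalyzable", "percent"] == 25   # 50/200
        assert by.loc["never_rop", "percent"] == 50      # 60/120
        assert by.loc["always_rop", "denominator"] == 120

    def test_zero_numerator_gives_zero_percent(self):
        acc = fm.cohort_accounting(fm.CohortCounts(100, 0, 0, 100, 100, 0, 0))
        by = acc.set_index("group")
        assert by.loc["cystic", "percent"] == 0

    def test_inconsistent_sums_name_the_identity(self):
        with pytest.raises(AccountingError, match="recruited"):
            fm.cohort_accounting(fm.CohortCounts(100, 10, 10, 70, 40, 20, 10))
        with pytest.raises(AccountingError, match="analyzed"):
            fm.cohort_accounting(fm.CohortCounts(100, 10, 10, 80, 40, 20, 10))

    def test_half_up_rounding(self):
        assert fm.cohort.round_half_up(21.5) == 22
        assert fm.cohort.round_half_up(21.49) == 21


class TestChiSquare:
    def test_equal_proportions_statistic_zero(self):
        stat, p = fm.chi_square_2x2([[30, 30], [20, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_expected_counts(self):
        obs = np.array([[30.0, 10.0], [20.0, 20.0]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = float(((obs - expected) ** 2 / expected).sum())
        stat, _ = fm.chi_square_2x2(obs)
        assert stat == pytest.approx(hand, rel=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedTestError):
            fm.chi_square_2x2([[0, 0], [20, 20]])


class TestValidation:
    def _table(self, **overrides):
        base = {
            "infant_id": ["a", "a"], "eye": ["right", "right"],
            "pma_weeks": [32.0, 34.0], "ga_weeks": [28.0, 28.0],
            "bw_g": [900.0, 900.0], "rop": ["absent", "absent"],
            "width_um": [1500.0, 1450.0],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_pma_out_of_range_names_column_and_row(self):
        with pytest.raises(CohortValidationError, match="pma_weeks.*row 1"):
            fm.validate_cohort(self._table(pma_weeks=[32.0, 50.0]))

    def test_ga_must_precede_visit(self):
        with pytest.raises(CohortValidationError, match="ga_weeks"):
            fm.validate_cohort(self._table(ga_weeks=[33.0, 28.0]))

    def test_excluded_rows_must_carry_no_metrics(self):
        bad = self._table(poor_quality=[True, False])
        with pytest.raises(CohortValidationError, match="row 0"):
            fm.validate_cohort(bad)


class TestTrajectoryModel:
    def test_noiseless_slopes_recovered_exactly(self):
        table, truth = fm.gen_cohort(fm.CohortSpec(
            n_infants=20, residual_sd=0.0, between_infant_sd=0.0, seed=5))
        res = fm.FovealTrajectoryModel(table, "width_um", adjustment="ga").fit()
        sl = res.slope_by_rop()
        assert sl["absent"]["estimate"] == pytest.approx(
            truth["width_slope_rop_absent"], abs=1e-6)
        assert sl["present"]["estimate"] == pytest.approx(
            truth["width_slope_rop_present"], abs=1e-6)

    def test_default_cohort_recovery_within_two_se(self, default_cohort):
        table, truth = default_cohort
        res = fm.FovealTrajectoryModel(table, "width_um", adjustment="ga").fit()
        sl = res.slope_by_rop()
        for grp, key in (("absent", "width_slope_rop_absent"),
                         ("present", "width_slope_rop_present")):
            z = abs(sl[grp]["estimate"] - truth[key]) / sl[grp]["se"]
            assert z < 2.0, (grp, sl[grp], truth[key])

    def test_interaction_detected_on_default_cohort(self, default_cohort):
        table, _ = default_cohort
        res = fm.FovealTrajectoryModel(table, "width_um", adjustment="ga").fit()
        assert res.rop_pma_interaction()["p"] < 0.001

    def test_ga_and_bw_never_share_a_model(self, default_cohort):
        table, _ = default_cohort
        m_ga = fm.FovealTrajectoryModel(table, "width_um", adjustment="ga")
        m_bw = fm.FovealTrajectoryModel(table, "width_um", adjustment="bw")
        assert "ga_c" in m_ga.formula and "bw_c100" not in m_ga.formula
        assert "bw_c100" in m_bw.formula and "ga_c" not in m_bw.formula

    def test_quadratic_term_included_on_request(self, default_cohort):
        table, _ = default_cohort
        m = fm.FovealTrajectoryModel(table, "cft_um", adjustment="ga",
                                     quadratic_pma=True)
        assert "I(pma_c ** 2)" in m.formula
        res = m.fit()
        assert "I(pma_c ** 2)" in res.fe_params.index

    def test_sided_response_melts_nasal_temporal(self, default_cohort):
        table, _ = default_cohort
        m = fm.FovealTrajectoryModel(table, "prt_um", adjustment="ga")
        assert m.sided
        assert "side" in m.data.columns
        res = m.fit()
        assert "C(side)[T.temporal]" in res.fe_params.index

    def test_predicted_mean_noiseless_equals_generating_intercept(self):
        table, truth = fm.gen_cohort(fm.CohortSpec(
            n_infants=20, residual_sd=0.0, between_infant_sd=0.0, seed=6))
        res = fm.FovealTrajectoryModel(table, "width_um", adjustment="ga").fit()
        pm = res.predict_means([
            {"pma_weeks": 32.0, "rop": "absent"},
            {"pma_weeks": 32.0, "rop": "present"},
        ])
        assert pm["mean"].iloc[0] == pytest.approx(
            truth["width_intercept_rop_absent"], abs=1e-6)
        assert pm["mean"].iloc[1] == pytest.approx(
            truth["width_intercept_rop_present"], abs=1e-6)

    def test_ratio_invariant_to_response_rescaling(self, default_cohort):
        table, _ = default_cohort
        mm = table.copy()
        mm["width_um"] = mm["width_um"] / 1000.0  # express in mm
        p_num = {"pma_weeks": 32.0, "rop": "present"}
        p_den = {"pma_weeks": 32.0, "rop": "absent"}
        r_um = fm.FovealTrajectoryModel(table, "width_um").fit() \
            .predicted_ratio(p_num, p_den)
        r_mm = fm.FovealTrajectoryModel(mm, "width_um", validate=False).fit() \
            .predicted_ratio(p_num, p_den)
        assert r_um == r_mm

    def test_extrapolation_flagged(self, default_cohort):
        table, _ = default_cohort
        res = fm.FovealTrajectoryModel(table, "width_um").fit()
        pm = res.predict_means([{"pma_weeks": 60.0, "rop": "absent"}])
        assert bool(pm["extrapolated"].iloc[0])

    def test_identical_profiles_ratio_100(self, default_cohort):
        table, _ = default_cohort
        res = fm.FovealTrajectoryModel(table, "width_um").fit()
        prof = {"pma_weeks": 35.0, "rop": "present"}
        assert res.predicted_ratio(prof, dict(prof)) == 100


class TestCoverage:
    def test_generating_slope_inside_ci_in_most_replicates(self):
        """95% Wald CIs on the ROP-absent slope should cover the generating
        value in at least 90% of seeded replicates."""
        hits = 0
        n_reps = 100
        for r in range(n_reps):
            table, truth = fm.gen_cohort(fm.CohortSpec(
                n_infants=80, seed=20_000 + r))
            res = fm.FovealTrajectoryModel(
                table, "width_um", adjustment="ga", extra_factors=False,
                validate=False).fit()
            sl = res.slope_by_rop()["absent"]
            lo = sl["estimate"] - 1.96 * sl["se"]
            hi = sl["estimate"] + 1.96 * sl["se"]
            hits += lo <= truth["width_slope_rop_absent"] <= hi
        assert hits / n_reps >= 0.90
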