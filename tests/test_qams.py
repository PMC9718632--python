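import numpy as np
import pytest

from chromqc.datasets import (
    load_calibration_lines,
    load_content_pairs,
    load_rcf_means,
    load_rcf_replicates,
    load_standard_concentrations,
)
from chromqc.qams import (
    CalibrationCurve,
    ContentReport,
    RCFMeasurement,
    RCFSet,
    RecoveryExperiment,
    SamplePrep,
    aggregate_rcf,
    check_rcf_reproducibility,
    esm_content,
    fit_calibration,
    qams_content,
    rcf,
    recovery_rate,
    relative_error,
    re_summary,
)

FA_237 = CalibrationCurve("forsythoside A", 237.0, 26.30, 0.073, 0.9995, (0.1776, 2.96))
PREP = SamplePrep()


class TestFitCalibration:
    def test_noiseless_published_line_recovered(self):
        amounts = np.linspace(0.1776, 2.96, 6)
        pts = [(a, 26.30 * a + 0.073) for a in amounts]
        fit = fit_calibration(pts, "forsythoside A", 237.0)
        assert fit.slope == pytest.approx(26.30, abs=1e-9)
        assert fit.intercept == pytest.approx(0.073, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.linear_range_ug == pytest.approx((0.1776, 2.96))

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_calibration([(0.1, 1.0), (0.2, 2.0)], "x", 237.0)

    def test_degenerate_amounts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration([(0.5, 1.0), (0.5, 1.1), (0.5, 0.9)], "x", 237.0)

    def test_matches_normal_equations_oracle_on_noisy_data(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0.1, 2.0, 8)
        y = 5.0 * x + 0.3 + rng.normal(0, 0.05, x.size)
        fit = fit_calibration(list(zip(x, y)), "x", 237.0)
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)


class TestEsmContent:
    def test_unit_amount_maps_to_ten_mg_per_g(self):
        # 1 µg on column, 0.5 g / 25 mL / 5 µL prep -> 10 mg/g
        assert esm_content(26.373, FA_237, PREP) == pytest.approx(10.0, rel=1e-9)

    def test_area_at_intercept_gives_zero_content(self):
        with pytest.warns(UserWarning, match="linear range"):
            assert esm_content(0.073, FA_237, PREP) == pytest.approx(0.0, abs=1e-12)

    def test_published_contents_invert_inside_linear_range(self):
        # batch contents of the internal standard correspond to on-column
        # amounts inside the published linear range
        pairs = load_content_pairs()
        fa = pairs[(pairs["analyte"] == "forsythoside A") & (pairs["wavelength_nm"] == 237)]
        for content in fa["esm_mg_g"]:
            amount = content / PREP.ug_on_column_to_mg_per_g
            assert 0.1776 <= amount <= 2.96

    def test_out_of_range_area_warns(self):
        with pytest.warns(UserWarning, match="linear range"):
            esm_content(200.0, FA_237, PREP)


class TestRcf:
    def test_identical_solution_gives_unity(self):
        m = RCFMeasurement("x", 237.0, W_is=10.0, A_is=5.0, W_x=10.0, A_x=5.0)
        assert rcf(m) == pytest.approx(1.0)

    def test_hand_computed_factor(self):
        m = RCFMeasurement("phillyrin", 237.0, W_is=296.0, A_is=100.0, W_x=27.5, A_x=7.79)
        assert rcf(m) == pytest.approx(0.8385, abs=1e-4)

    def test_invariant_under_common_area_rescale(self):
        m1 = RCFMeasurement("x", 237.0, 296.0, 100.0, 27.5, 7.79)
        m2 = RCFMeasurement("x", 237.0, 296.0, 100.0 * 3.7, 27.5, 7.79 * 3.7)
        assert rcf(m1) == pytest.approx(rcf(m2), rel=1e-12)

    def test_invariant_under_common_concentration_rescale(self):
        m1 = RCFMeasurement("x", 237.0, 296.0, 100.0, 27.5, 7.79)
        m2 = RCFMeasurement("x", 237.0, 296.0 * 0.2, 100.0, 27.5 * 0.2, 7.79)
        assert rcf(m1) == pytest.approx(rcf(m2), rel=1e-12)

    def test_published_lines_predict_published_factors(self):
        # correction factors implied by the calibration lines at the mixed
        # standard concentrations agree with the published means to ~1%
        lines = load_calibration_lines()
        concs = load_standard_concentrations()
        means = load_rcf_means()
        for row in means.itertuples():
            wl = float(row.wavelength_nm)
            get = lambda an: lines[
                (lines["analyte"] == an) & (lines["wavelength_nm"] == wl)
            ].iloc[0]
            lx, lis = get(row.analyte), get("forsythoside A")
            amount = lambda c: c * 5.0 / 1000.0  # 5 µL of c µg/mL
            a_x = lx.slope * amount(concs[row.analyte]) + lx.intercept
            a_is = lis.slope * amount(concs["forsythoside A"]) + lis.intercept
            f = rcf(
                RCFMeasurement(
                    row.analyte, wl, concs["forsythoside A"], a_is, concs[row.analyte], a_x
                )
            )
            assert f == pytest.approx(row.mean_f, rel=0.015)


class TestAggregateRcf:
    def test_published_replicate_means_reproduced(self):
        reps = load_rcf_replicates()
        means = load_rcf_means()
        for row in means.itertuples():
            f = reps[reps["analyte"] == row.analyte]["f"]
            agg = aggregate_rcf(f, row.analyte, float(row.wavelength_nm))
            assert agg.mean_f == row.mean_f

    def test_identical_replicates_have_zero_rsd(self):
        agg = aggregate_rcf([1.5, 1.5, 1.5], "x", 237.0)
        assert agg.rsd_pct == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rcf([1.5], "x", 237.0)


class TestRcfReproducibility:
    @staticmethod
    def rcf_set(mean, analyte="x"):
        return RCFSet(analyte, 237.0, (mean,) * 2, mean, 0.0)

    def test_identical_conditions_pass_at_zero(self):
        report = check_rcf_reproducibility([self.rcf_set(1.5), self.rcf_set(1.5)])
        assert report["rsd_pct"].iloc[0] == 0.0
        assert bool(report["passed"].iloc[0])

    def test_ten_percent_shift_fails_three_percent_gate(self):
        report = check_rcf_reproducibility([self.rcf_set(1.5), self.rcf_set(1.65)])
        assert not bool(report["passed"].iloc[0])

    def test_single_condition_group_is_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            report = check_rcf_reproducibility([self.rcf_set(1.5)])
        assert report.empty


class TestQamsContent:
    def test_equal_areas_unit_factor_returns_is_content(self):
        assert qams_content(5.0, 1.0, 5.0, 2.0) == pytest.approx(2.0)

    def test_hand_computed_content(self):
        assert qams_content(25.0, 0.5, 50.0, 2.0) == pytest.approx(2.0)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            qams_content(1.0, 0.0, 1.0, 1.0)

    def test_zero_intercept_identity_with_esm(self):
        """With zero intercepts and a shared calibration, single-marker
        quantitation reproduces the external-standard result exactly."""
        prep = SamplePrep()
        s_is, s_x = 26.30, 21.89
        curve_is = CalibrationCurve("is", 237.0, s_is, 0.0, 1.0, (0.01, 10.0))
        curve_x = CalibrationCurve("x", 237.0, s_x, 0.0, 1.0, (0.01, 10.0))
        # factor measured on a mixed standard through the same curves
        w_is, w_x = 296.0, 27.5
        f = rcf(
            RCFMeasurement(
                "x", 237.0, w_is, s_is * w_is, w_x, s_x * w_x
            )
        )
        for amount_x, amount_is in [(0.11, 1.48), (0.2, 0.9), (2.0, 0.3)]:
            a_x, a_is = s_x * amount_x, s_is * amount_is
            esm = esm_content(a_x, curve_x, prep)
            is_content = esm_content(a_is, curve_is, prep)
            assert qams_content(a_x, f, a_is, is_content) == pytest.approx(
                esm, rel=1e-10
            )


class TestRecoveryRate:
    def test_full_recovery(self):
        assert recovery_rate(RecoveryExperiment(20.0, 10.0, 10.0)) == 100.0

    def test_nothing_recovered(self):
        assert recovery_rate(RecoveryExperiment(10.0, 10.0, 10.0)) == 0.0

    def test_hand_computed(self):
        assert recovery_rate(RecoveryExperiment(19.6, 10.0, 10.0)) == pytest.approx(96.0)

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(ValueError):
            RecoveryExperiment(19.6, 10.0, 0.0)


class TestRelativeError:
    @pytest.mark.parametrize(
        "qams, esm, expected",
        [(0.862, 0.868, -0.69), (0.094, 0.093, 1.08), (5.062, 5.077, -0.30)],
    )
    def test_published_pairs(self, qams, esm, expected):
        assert relative_error(qams, esm) == expected

    def test_identical_contents_give_zero(self):
        assert relative_error(1.234, 1.234) == 0.0

    def test_nonpositive_esm_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestReSummary:
    @staticmethod
    def reports_from_published():
        pairs = load_content_pairs(pairs_only=True)
        return [
            ContentReport(
                str(r.batch),
                r.analyte,
                float(r.wavelength_nm),
                float(r.esm_mg_g),
                float(r.qams_mg_g),
                relative_error(float(r.qams_mg_g), float(r.esm_mg_g)),
            )
            for r in pairs.itertuples()
        ]

    def test_published_pairs_span_expected_range(self):
        reports = self.reports_from_published()
        assert len(reports) == 60
        lo, hi, by_analyte = re_summary(reports)
        assert lo == -0.83
        assert hi == 1.08
        assert len(by_analyte) == 6

    def test_single_report_min_equals_max(self):
        r = ContentReport("1", "x", 237.0, 1.0, 1.01, 1.0)
        lo, hi, _ = re_summary([r])
        assert lo == hi == 1.0

    def test_extrema_permutation_invariant(self):
        reports = self.reports_from_published()
        lo1, hi1, _ = re_summary(reports)
        lo2, hi2, _ = re_summary(list(reversed(reports)))
        assert (lo1, hi1) == (lo2, hi2)
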