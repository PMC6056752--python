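"""Calibration fitting, back-calculation, and ratio analyses."""

import numpy as np
import pytest

from mrmquant.quant import (
    CalibrationCurve,
    MrmMeasurement,
    back_calculate,
    fit_calibration,
    heterogeneity_content,
    normalize,
    oxidation_ratio,
    serial_dilution_levels,
)


def calibrator(conc, response, istd=1.0e5, run="run1"):
    return MrmMeasurement(
        sample_id=f"cal-{conc}",
        role="calibrator",
        transition_label="q",
        analyte_area=istd * response,
        istd_area=istd,
        nominal_conc=conc,
        run_id=run,
    )


def noise_free_calibrators(slope=0.02, intercept=0.0, top=100.0, n=10):
    return [
        calibrator(c, slope * c + intercept)
        for c in serial_dilution_levels(top, n)
    ]


class TestNormalize:
    def test_ratio(self):
        m = calibrator(1.0, 1.0)
        assert normalize(m) == 1.0

    def test_zero_analyte(self):
        m = MrmMeasurement("s", "blank", "q", 0.0, 500.0)
        assert normalize(m) == 0.0

    def test_scale_invariance(self):
        a = MrmMeasurement("s", "unknown", "q", 123.0, 456.0)
        b = MrmMeasurement("s", "unknown", "q", 246.0, 912.0)
        assert normalize(a) == pytest.approx(normalize(b))

    def test_failed_injection(self):
        m = MrmMeasurement("s", "blank", "q", 1.0, 0.0)
        with pytest.raises(ValueError, match="ISTD"):
            normalize(m)


class TestSerialDilution:
    def test_ten_level_twofold_from_100(self):
        levels = serial_dilution_levels(100.0, 10)
        assert levels[0] == 100.0
        assert round(levels[-1], 3) == 0.195
        assert len(levels) == 10


class TestFitCalibration:
    def test_noise_free_recovers_truth(self):
        curve = fit_calibration(noise_free_calibrators())
        assert curve.slope == pytest.approx(0.02, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        for acc in curve.level_back_accuracies.values():
            assert acc == pytest.approx(100.0, rel=1e-9)
        assert curve.failing_levels == ()
        assert curve.usable_range == (
            pytest.approx(100.0 / 2**9),
            pytest.approx(100.0),
        )

    def test_requires_six_levels(self):
        cal = [calibrator(c, 0.02 * c) for c in (1, 2, 4, 8, 16)]
        with pytest.raises(ValueError, match="6 distinct levels"):
            fit_calibration(cal)

    def test_identical_concentrations_rejected(self):
        cal = [calibrator(5.0, 0.1) for _ in range(8)]
        with pytest.raises(ValueError):
            fit_calibration(cal)

    def test_weighting_rescale_invariance(self):
        # rescaling all responses scales the slope, accuracies unchanged
        base = fit_calibration(noise_free_calibrators(slope=0.02))
        scaled = fit_calibration(noise_free_calibrators(slope=0.06))
        assert scaled.slope == pytest.approx(3 * base.slope)
        assert list(scaled.level_back_accuracies.values()) == pytest.approx(
            list(base.level_back_accuracies.values())
        )

    def test_bad_level_flagged(self):
        cal = noise_free_calibrators()
        # corrupt the second-lowest level by +30%
        level = sorted(m.nominal_conc for m in cal)[1]
        cal = [
            calibrator(m.nominal_conc, 0.02 * m.nominal_conc * 1.3)
            if m.nominal_conc == level
            else m
            for m in cal
        ]
        curve = fit_calibration(cal)
        assert level in curve.failing_levels

    def test_slope_recovery_under_noise(self):
        # lognormal CV 5% noise; fitted slope within 3 simulated SE of truth
        truth = 0.02
        rng = np.random.default_rng(2024)
        sigma = np.sqrt(np.log1p(0.05**2))
        slopes = []
        for _ in range(300):
            eps = rng.lognormal(-sigma**2 / 2, sigma, size=10)
            cal = [
                calibrator(c, truth * c * e)
                for c, e in zip(serial_dilution_levels(100.0, 10), eps)
            ]
            slopes.append(fit_calibration(cal).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - truth) < 3 * se


class TestBackCalculate:
    def test_round_trip(self):
        curve = fit_calibration(noise_free_calibrators())
        m = calibrator(12.5, 0.02 * 12.5)
        assert back_calculate(curve, m).conc == pytest.approx(12.5)

    def test_response_at_intercept_is_zero(self):
        curve = CalibrationCurve(slope=0.02, intercept=0.005)
        m = MrmMeasurement("s", "unknown", "q", 0.005 * 1e5, 1e5)
        assert back_calculate(curve, m).conc == pytest.approx(0.0, abs=1e-12)

    def test_below_zero_clamped_and_flagged(self):
        curve = CalibrationCurve(slope=0.02, intercept=0.01)
        m = MrmMeasurement("s", "unknown", "q", 0.0, 1e5)
        result = back_calculate(curve, m)
        assert result.conc == 0.0
        assert "below_zero" in result.flags

    def test_above_range_flagged(self):
        curve = fit_calibration(noise_free_calibrators())
        m = MrmMeasurement("s", "unknown", "q", 0.02 * 200.0 * 1e5, 1e5)
        assert "above_range" in back_calculate(curve, m).flags


class TestHeterogeneity:
    def test_percent_of_max_and_shares(self):
        out = heterogeneity_content({"v1": 100.0, "v2": 37.0, "v3": 4.87})
        by_label = {v.label: v for v in out}
        assert by_label["v1"].percent_of_max == 100.0
        assert by_label["v2"].percent_of_max == 37.0
        assert by_label["v3"].percent_of_max == 4.87
        assert by_label["v1"].share_pct == pytest.approx(70.5, abs=0.05)
        assert by_label["v2"].share_pct == pytest.approx(26.1, abs=0.05)
        assert by_label["v3"].share_pct == pytest.approx(3.43, abs=0.05)

    def test_shares_sum_to_100(self):
        out = heterogeneity_content({"a": 3.0, "b": 2.0, "c": 1.0})
        assert sum(v.share_pct for v in out) == pytest.approx(100.0, abs=0.2)

    def test_single_dominant(self):
        out = heterogeneity_content({"a": 5.0, "b": 0.0})
        assert [v.percent_of_max for v in out] == [100.0, 0.0]

    def test_scale_invariance_and_permutation(self):
        a = heterogeneity_content({"x": 10.0, "y": 5.0})
        b = heterogeneity_content({"y": 50.0, "x": 100.0})
        assert {v.label: v.percent_of_max for v in a} == {
            v.label: v.percent_of_max for v in b
        }

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_content({"a": 0.0, "b": 0.0})

    def test_requires_two_variants(self):
        with pytest.raises(ValueError):
            heterogeneity_content({"a": 1.0})


class TestOxidationRatio:
    def test_control_is_100(self):
        out = oxidation_ratio(
            {"control": (2.0, None), "treated": (2.0, 1.0)}, "control", "treated"
        )
        by = {r.condition: r for r in out}
        assert by["control"].monomer_pct == 100.0
        assert by["treated"].monomer_pct == 100.0
        assert by["treated"].dimer_pct == 100.0

    def test_strong_oxidation_ratio(self):
        out = oxidation_ratio(
            {"control": (2.0, None), "H2O2": (2.0 * 0.00255, 1.5)},
            "control",
            "H2O2",
        )
        by = {r.condition: r for r in out}
        assert by["H2O2"].monomer_pct == pytest.approx(0.255, abs=1e-9)

    def test_not_detected_propagates_as_none(self):
        out = oxidation_ratio(
            {"control": (2.0, None), "H2O2": (0.1, 1.0)}, "control", "H2O2"
        )
        control = next(r for r in out if r.condition == "control")
        assert control.dimer_pct is None  # N.D., never 0.0

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            oxidation_ratio({"a": (1.0, 1.0)}, "control", "a")
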