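"""Precision/accuracy statistics and guideline acceptance rules."""

import numpy as np
import pytest

from mrmquant._rounding import round_sigfig
from mrmquant.quant import MrmMeasurement
from mrmquant.validation import (
    ETANERCEPT_QC,
    GuidelineThresholds,
    LevelStats,
    QcDesign,
    ValidationReport,
    accuracy_percent,
    build_report,
    cv_percent,
    guideline_check,
    run_statistics,
    selectivity_check,
)


class TestRunStatistics:
    def test_sd_uses_n_minus_1(self):
        stats = run_statistics([1.0, 2.0, 3.0], nominal=2.0)
        assert stats.sd == pytest.approx(1.0)
        assert stats.mean == pytest.approx(2.0)
        assert stats.accuracy_pct == pytest.approx(100.0)

    def test_identical_replicates(self):
        stats = run_statistics([5.0] * 5, nominal=4.0)
        assert stats.sd == 0.0
        assert stats.cv_pct == 0.0
        assert stats.accuracy_pct == pytest.approx(125.0)

    def test_zero_mean_cv_not_computable(self):
        stats = run_statistics([0.0, 0.0], nominal=1.0)
        assert stats.cv_pct is None

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            run_statistics([1.0], nominal=1.0)

    def test_cells_recompute_from_reported_mean_sd_nominal(self):
        # printed-table arithmetic at 3 significant figures
        assert cv_percent(68.4, 2.51) == 3.67
        assert accuracy_percent(68.4, 80.0) == 85.5
        assert accuracy_percent(9.90, 9.38) == 106.0

    def test_reported_cells_self_consistent_on_synthetic_reports(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = rng.lognormal(2.0, 0.1, size=5)
            nominal = float(rng.uniform(5, 10))
            stats = run_statistics(values, nominal).rounded()
            assert cv_percent(stats.mean, stats.sd) == pytest.approx(
                stats.cv_pct, rel=0.02
            )
            assert accuracy_percent(stats.mean, stats.nominal) == pytest.approx(
                stats.accuracy_pct, rel=0.02
            )


class TestQcDesign:
    def test_levels_must_increase(self):
        with pytest.raises(ValueError):
            QcDesign(levels={"LLOQ": 1.0, "LQC": 0.5})

    def test_etanercept_design(self):
        assert list(ETANERCEPT_QC.levels.values()) == [0.195, 0.586, 9.38, 80.0]
        assert ETANERCEPT_QC.lloq_label == "LLOQ"


def make_report(level_values, design=ETANERCEPT_QC):
    concentrations = {
        ("run1", level): values for level, values in level_values.items()
    }
    return build_report(concentrations, design)


class TestGuidelineCheck:
    def test_passing_study(self):
        # pooled cells with accuracies ~100 and CVs < 10 pass every level
        report = make_report(
            {
                level: list(np.linspace(0.95, 1.05, 5) * nominal)
                for level, nominal in ETANERCEPT_QC.levels.items()
            }
        )
        checked = guideline_check(report)
        assert all(checked.verdicts.values())
        assert checked.overall_pass

    def test_biased_level_fails(self):
        values = {
            level: list(np.linspace(0.98, 1.02, 5) * nominal)
            for level, nominal in ETANERCEPT_QC.levels.items()
        }
        values["LQC"] = [0.79 * 0.586] * 3 + [0.79 * 0.586 * 1.01] * 2
        checked = guideline_check(make_report(values))
        assert not checked.verdicts["LQC"]
        assert not checked.overall_pass

    def test_cv_boundary_inclusive(self):
        stats = LevelStats(
            level="MQC", nominal=9.38, n=5, mean=9.38, sd=9.38 * 0.15,
            cv_pct=15.0, accuracy_pct=100.0,
        )
        report = ValidationReport(
            design=ETANERCEPT_QC,
            per_run={},
            pooled={
                "LLOQ": LevelStats("LLOQ", 0.195, 5, 0.195, 0.0, 0.0, 100.0),
                "MQC": stats,
            },
        )
        assert guideline_check(report).verdicts["MQC"]

    def test_lloq_gets_relaxed_tolerance(self):
        values = {
            level: list(np.linspace(0.99, 1.01, 5) * nominal)
            for level, nominal in ETANERCEPT_QC.levels.items()
        }
        values["LLOQ"] = [0.82 * 0.195 * f for f in (0.99, 1.0, 1.0, 1.0, 1.01)]
        checked = guideline_check(make_report(values))
        assert checked.verdicts["LLOQ"]  # 18% bias allowed at LLOQ

    def test_missing_lloq_rejected(self):
        report = make_report(
            {"MQC": [9.0, 9.5, 9.4], "HQC": [80.0, 81.0, 79.0]}
        )
        with pytest.raises(ValueError, match="LLOQ"):
            guideline_check(report)

    def test_calibration_rule(self):
        report = make_report(
            {
                level: list(np.linspace(0.98, 1.02, 5) * nominal)
                for level, nominal in ETANERCEPT_QC.levels.items()
            }
        )
        ten_good = {float(2**i): 100.0 for i in range(10)}
        assert guideline_check(report, calibration_accuracies=ten_good).calibration_pass
        three_bad = dict(ten_good)
        for level in list(three_bad)[-3:]:
            three_bad[level] = 130.0
        checked = guideline_check(report, calibration_accuracies=three_bad)
        assert not checked.calibration_pass
        assert not checked.overall_pass

    def test_tightening_thresholds_monotone(self):
        values = {
            level: list(np.linspace(0.9, 1.1, 5) * nominal)
            for level, nominal in ETANERCEPT_QC.levels.items()
        }
        report = make_report(values)
        loose = guideline_check(report)
        tight = guideline_check(
            report,
            thresholds=GuidelineThresholds(
                accuracy_tol_pct=5.0, accuracy_tol_lloq_pct=5.0,
                cv_max_pct=5.0, cv_max_lloq_pct=5.0,
            ),
        )
        for level in loose.verdicts:
            assert loose.verdicts[level] or not tight.verdicts[level]

    def test_pooled_mean_is_replicate_weighted_run_mean(self):
        concentrations = {
            ("run1", "LLOQ"): [0.18, 0.20, 0.21],
            ("run2", "LLOQ"): [0.19, 0.20, 0.22],
        }
        for level, nominal in list(ETANERCEPT_QC.levels.items())[1:]:
            concentrations[("run1", level)] = [nominal] * 3
        report = build_report(concentrations, ETANERCEPT_QC)
        run_means = [
            report.per_run["run1"]["LLOQ"].mean,
            report.per_run["run2"]["LLOQ"].mean,
        ]
        assert report.pooled["LLOQ"].mean == pytest.approx(np.mean(run_means))
        assert report.pooled["LLOQ"].n == 6


class TestSelectivity:
    def blank(self, analyte=0.0, istd=10.0):
        return MrmMeasurement("blank", "blank", "q", analyte, istd)

    def lloq(self, analyte=1000.0, istd=1.0e5):
        return MrmMeasurement("lloq", "qc", "q", analyte, istd, nominal_conc=0.195)

    def test_clean_blank_passes(self):
        assert selectivity_check([self.blank()], [self.lloq()])

    def test_blank_equal_to_lloq_fails(self):
        assert not selectivity_check([self.blank(analyte=1000.0)], [self.lloq()])

    def test_twenty_percent_boundary_inclusive(self):
        assert selectivity_check([self.blank(analyte=200.0)], [self.lloq()])

    def test_requires_lloq(self):
        with pytest.raises(ValueError):
            selectivity_check([self.blank()], [])


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(105.54, 106.0), (3.6696, 3.67), (0.19549, 0.195), (99.25, 99.3)],
    )
    def test_three_sigfig_half_away(self, value, expected):
        assert round_sigfig(value) == expected
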