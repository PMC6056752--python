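"""End-to-end study evaluation: peak areas in, verdicted report out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .quant import CalibrationCurve, MrmMeasurement, back_calculate, fit_calibration
from .validation import (
    GuidelineThresholds,
    QcDesign,
    ValidationReport,
    build_report,
    guideline_check,
    selectivity_check,
)


@dataclass(frozen=True)
class StudyResult:
    """Everything a validation study produces."""

    curve: CalibrationCurve
    report: ValidationReport
    selectivity_pass: bool | None


def validate_study(
    measurements: Sequence[MrmMeasurement],
    design: QcDesign,
    weighting: str = "1/x^2",
    thresholds: GuidelineThresholds = GuidelineThresholds(),
) -> StudyResult:
    """Fit calibration, back-calculate the QCs, and apply guideline rules.

    QC levels are matched to the design by nominal concentration.  The
    selectivity check runs when the measurement set contains blanks;
    otherwise it is reported as ``None`` (not assessed).
    """
    calibrators = [m for m in measurements if m.role == "calibrator"]
    curve = fit_calibration(calibrators, weighting=weighting)
    conc_by_nominal = {v: k for k, v in design.levels.items()}
    grouped: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        if m.role != "qc":
            continue
        level = conc_by_nominal.get(m.nominal_conc)
        if level is None:
            raise ValueError(
                f"QC sample {m.sample_id!r} at {m.nominal_conc} ug/mL matches "
                "no design level"
            )
        grouped.setdefault((m.run_id, level), []).append(
            back_calculate(curve, m).conc
        )
    report = guideline_check(
        build_report(grouped, design),
        thresholds=thresholds,
        calibration_accuracies=curve.level_back_accuracies,
    )
    blanks = [m for m in measurements if m.role == "blank"]
    lloq_label = design.lloq_label
    lloq_nominal = design.levels[lloq_label]
    lloq_samples = [
        m for m in measurements if m.role == "qc" and m.nominal_conc == lloq_nominal
    ]
    selectivity: bool | None = None
    if blanks and lloq_samples:
        selectivity = selectivity_check(blanks, lloq_samples, thresholds=thresholds)
    return StudyResult(curve=curve, report=report, selectivity_pass=selectivity)
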