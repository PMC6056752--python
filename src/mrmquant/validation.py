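"""Precision/accuracy validation tables and guideline acceptance rules.

A quantitative bioanalytical method is validated by measuring quality
control (QC) samples at four levels — the lower limit of quantification
(LLOQ) and low/middle/high QC — in several replicates over several runs,
then summarising each run and the pooled set per level:

* mean and SD of the back-calculated concentrations (SD with the n-1
  denominator),
* precision as CV% = 100 * SD / mean,
* accuracy as 100 * mean / nominal.

Acceptance follows the 15/20% rule of bioanalytical method validation
guidelines: per level, accuracy within +/-15% of nominal and CV <= 15%,
both relaxed to 20% at the LLOQ; the calibration curve passes when at
least 75% of its levels (and no fewer than 6) back-calculate within the
same tolerances.  Thresholds are inclusive at the boundary and
configurable.  Reported cells are rounded half-away-from-zero to 3
significant figures; the verdicts are computed on unrounded values.

Pooled statistics are recomputed from all individual replicate values,
not assembled from per-run summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rounding import round_sigfig
from .quant import MrmMeasurement, normalize

POOLED = "pooled"


@dataclass(frozen=True)
class QcDesign:
    """QC levels (label -> nominal ug/mL), replicates per run, and run count."""

    levels: Mapping[str, float]
    replicates_per_run: int = 5
    runs: int = 3

    def __post_init__(self) -> None:
        values = list(self.levels.values())
        if any(v <= 0 for v in values):
            raise ValueError("nominal concentrations must be positive")
        if values != sorted(values) or len(set(values)) != len(values):
            raise ValueError(
                "nominal concentrations must be strictly increasing LLOQ -> HQC"
            )
        if self.replicates_per_run < 1 or self.runs < 1:
            raise ValueError("replicates_per_run and runs must be positive")

    @property
    def lloq_label(self) -> str:
        return next(iter(self.levels))


#: QC design used in the Etanercept serum validation study.
ETANERCEPT_QC = QcDesign(
    levels={"LLOQ": 0.195, "LQC": 0.586, "MQC": 9.38, "HQC": 80.0}
)
#: QC design used in the Abatacept serum validation study.
ABATACEPT_QC = QcDesign(
    levels={"LLOQ": 0.391, "LQC": 0.586, "MQC": 9.38, "HQC": 80.0}
)


@dataclass(frozen=True)
class LevelStats:
    """Mean/SD/CV%/accuracy% of one QC level in one run (or pooled)."""

    level: str
    nominal: float  # ug/mL
    n: int
    mean: float  # ug/mL
    sd: float  # ug/mL
    cv_pct: float | None  # None when mean == 0 (CV undefined)
    accuracy_pct: float

    def rounded(self) -> "LevelStats":
        return LevelStats(
            level=self.level,
            nominal=self.nominal,
            n=self.n,
            mean=round_sigfig(self.mean),
            sd=round_sigfig(self.sd),
            cv_pct=None if self.cv_pct is None else round_sigfig(self.cv_pct),
            accuracy_pct=round_sigfig(self.accuracy_pct),
        )


def run_statistics(
    concentrations: Sequence[float], nominal: float, level: str = ""
) -> LevelStats:
    """Mean, SD (n-1), CV% and accuracy% of replicate back-calculations."""
    if len(concentrations) < 2:
        raise ValueError("run statistics require at least 2 replicates")
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    values = np.asarray(concentrations, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = None if mean == 0 else 100.0 * sd / mean
    return LevelStats(
        level=level,
        nominal=nominal,
        n=len(values),
        mean=mean,
        sd=sd,
        cv_pct=cv,
        accuracy_pct=100.0 * mean / nominal,
    )


def cv_percent(mean: float, sd: float) -> float:
    """CV% recomputed from a reported mean/SD cell, at 3 significant figures."""
    if mean == 0:
        raise ValueError("CV undefined at zero mean")
    return round_sigfig(100.0 * sd / mean)


def accuracy_percent(mean: float, nominal: float) -> float:
    """Accuracy% recomputed from a reported mean and nominal, 3 sig. figures."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return round_sigfig(100.0 * mean / nominal)


@dataclass(frozen=True)
class GuidelineThresholds:
    """Acceptance tolerances of the 15/20% guideline rule (inclusive)."""

    accuracy_tol_pct: float = 15.0
    accuracy_tol_lloq_pct: float = 20.0
    cv_max_pct: float = 15.0
    cv_max_lloq_pct: float = 20.0
    cal_fraction_required: float = 0.75
    cal_min_levels: int = 6
    selectivity_blank_max_pct: float = 20.0
    selectivity_istd_max_pct: float = 5.0


@dataclass(frozen=True)
class ValidationReport:
    """Per-run and pooled level statistics with guideline verdicts."""

    design: QcDesign
    per_run: Mapping[str, Mapping[str, LevelStats]]  # run_id -> level -> stats
    pooled: Mapping[str, LevelStats]  # level -> stats
    verdicts: Mapping[str, bool] = field(default_factory=dict)
    calibration_pass: bool | None = None
    overall_pass: bool | None = None


def build_report(
    concentrations: Mapping[tuple[str, str], Sequence[float]],
    design: QcDesign,
) -> ValidationReport:
    """Assemble per-run and pooled statistics from back-calculated values.

    ``concentrations`` maps ``(run_id, level_label)`` to that run's
    replicate back-calculations.  Pooled cells recompute over all values.
    """
    per_run: dict[str, dict[str, LevelStats]] = {}
    pooled_values: dict[str, list[float]] = {lv: [] for lv in design.levels}
    for (run_id, level), values in concentrations.items():
        if level not in design.levels:
            raise ValueError(f"unknown QC level {level!r}")
        stats = run_statistics(values, design.levels[level], level=level)
        per_run.setdefault(run_id, {})[level] = stats
        pooled_values[level].extend(values)
    pooled = {
        level: run_statistics(values, design.levels[level], level=level)
        for level, values in pooled_values.items()
        if values
    }
    return ValidationReport(design=design, per_run=per_run, pooled=pooled)


def _level_pass(
    stats: LevelStats, is_lloq: bool, thresholds: GuidelineThresholds
) -> bool:
    acc_tol = thresholds.accuracy_tol_lloq_pct if is_lloq else thresholds.accuracy_tol_pct
    cv_max = thresholds.cv_max_lloq_pct if is_lloq else thresholds.cv_max_pct
    if stats.cv_pct is None:
        return False
    return abs(stats.accuracy_pct - 100.0) <= acc_tol and stats.cv_pct <= cv_max


def guideline_check(
    report: ValidationReport,
    thresholds: GuidelineThresholds = GuidelineThresholds(),
    calibration_accuracies: Mapping[float, float] | None = None,
) -> ValidationReport:
    """Apply guideline acceptance rules and return the verdicted report.

    Per-level verdicts are evaluated on the pooled statistics; the overall
    verdict is the conjunction of all level verdicts and — when
    ``calibration_accuracies`` (level -> back-calculated accuracy %) is
    supplied — of the calibration rule: at least ``cal_min_levels`` levels
    and at least 75% of them within +/-15% (+/-20% at the lowest level).
    """
    if report.design.lloq_label not in report.pooled:
        raise ValueError("report is missing the LLOQ level")
    lloq = report.design.lloq_label
    verdicts = {
        level: _level_pass(stats, level == lloq, thresholds)
        for level, stats in report.pooled.items()
    }
    cal_pass: bool | None = None
    if calibration_accuracies is not None:
        levels = sorted(calibration_accuracies)
        lowest = levels[0]
        ok = 0
        for level in levels:
            tol = (
                thresholds.accuracy_tol_lloq_pct
                if level == lowest
                else thresholds.accuracy_tol_pct
            )
            if abs(calibration_accuracies[level] - 100.0) <= tol:
                ok += 1
        cal_pass = (
            len(levels) >= thresholds.cal_min_levels
            and ok >= thresholds.cal_fraction_required * len(levels)
            and ok >= thresholds.cal_min_levels
        )
    overall = all(verdicts.values()) and (cal_pass is not False)
    return ValidationReport(
        design=report.design,
        per_run=report.per_run,
        pooled=report.pooled,
        verdicts=verdicts,
        calibration_pass=cal_pass,
        overall_pass=overall,
    )


def selectivity_check(
    blanks: Sequence[MrmMeasurement],
    lloq_samples: Sequence[MrmMeasurement],
    istd_reference: Sequence[MrmMeasurement] | None = None,
    thresholds: GuidelineThresholds = GuidelineThresholds(),
) -> bool:
    """Interference check on blank matrix.

    Passes when the mean blank analyte response is at most 20% of the mean
    LLOQ analyte response and the mean blank ISTD-channel area is at most
    5% of the mean ISTD area of the reference samples (the LLOQ samples
    when no separate reference is given).  Boundaries inclusive.
    """
    if not blanks:
        raise ValueError("selectivity requires at least one blank")
    if not lloq_samples:
        raise ValueError("selectivity requires at least one LLOQ sample")
    blank_analyte = float(np.mean([m.analyte_area for m in blanks]))
    lloq_analyte = float(np.mean([m.analyte_area for m in lloq_samples]))
    if lloq_analyte <= 0:
        raise ValueError("LLOQ analyte response must be positive")
    analyte_ok = blank_analyte <= thresholds.selectivity_blank_max_pct / 100.0 * lloq_analyte
    reference = istd_reference if istd_reference else lloq_samples
    istd_ref = float(np.mean([m.istd_area for m in reference]))
    blank_istd = float(np.mean([m.istd_area for m in blanks]))
    istd_ok = blank_istd <= thresholds.selectivity_istd_max_pct / 100.0 * istd_ref
    return analyte_ok and istd_ok
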