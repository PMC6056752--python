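"""ISTD-normalized MRM quantitation: calibration, ratios, heterogeneity.

Every peak area is first normalized to the co-injected internal-standard
(ISTD) peptide area from the same run, cancelling injection and ionization
variability.  Calibration fits a weighted linear model of normalized
response on nominal concentration (1/x^2 weighting by default, the
standard choice for bioanalytical LC-MS calibrations spanning about three
orders of magnitude), back-calculates each calibrator, and flags levels
whose back-calculated accuracy misses +/-15% (+/-20% at the lowest level).

Two ratio analyses reuse the same normalized responses:

* N-terminal heterogeneity content — variant peptides sharing a common
  y-fragment are expressed as percent of the most abundant variant (the
  maximum scaled to 100), plus each variant's share of the variant total;
* oxidation state — monomer and disulfide-dimer responses expressed as
  percent of their respective reference condition, with not-detected
  species propagated as ``None`` (printed ``N.D.``), never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from ._rounding import round_sigfig

Role = Literal["blank", "zero", "calibrator", "qc", "unknown"]

#: Back-calculated accuracy tolerance for calibrators, percent of nominal.
CAL_TOLERANCE_PCT = 15.0
CAL_TOLERANCE_LLOQ_PCT = 20.0


@dataclass(frozen=True)
class MrmMeasurement:
    """One MRM peak-area observation (analyte + ISTD channel)."""

    sample_id: str
    role: Role
    transition_label: str
    analyte_area: float
    istd_area: float
    nominal_conc: float | None = None  # ug/mL
    run_id: str = "run1"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.analyte_area < 0:
            raise ValueError(
                f"negative analyte area in sample {self.sample_id!r}"
            )
        if self.role in ("calibrator", "qc") and self.nominal_conc is None:
            raise ValueError(
                f"{self.role} sample {self.sample_id!r} requires nominal_conc"
            )


def normalize(measurement: MrmMeasurement) -> float:
    """ISTD-normalized response: analyte area / ISTD area (dimensionless)."""
    if measurement.istd_area <= 0:
        raise ValueError(
            f"non-positive ISTD area in sample {measurement.sample_id!r} "
            "(failed injection)"
        )
    return measurement.analyte_area / measurement.istd_area


def serial_dilution_levels(top: float = 100.0, n_levels: int = 10, fold: float = 2.0) -> list[float]:
    """Concentrations of an ``n_levels``-point ``fold``-serial dilution, high to low."""
    if top <= 0 or n_levels < 1 or fold <= 1:
        raise ValueError("need top > 0, n_levels >= 1, fold > 1")
    return [top / fold**i for i in range(n_levels)]


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear calibration of normalized response on concentration."""

    slope: float
    intercept: float
    weighting_label: str = "1/x^2"
    level_back_accuracies: Mapping[float, float] = field(default_factory=dict)
    failing_levels: tuple[float, ...] = ()
    usable_range: tuple[float, float] = (0.0, 0.0)


_WEIGHTS = {
    "none": lambda c: np.ones_like(c),
    "1/x": lambda c: 1.0 / c,
    "1/x^2": lambda c: 1.0 / c**2,
}


def fit_calibration(
    calibrators: Sequence[MrmMeasurement],
    weighting: str = "1/x^2",
) -> CalibrationCurve:
    """Fit a weighted least-squares calibration line through the calibrators.

    Requires at least 6 distinct concentration levels.  Back-calculated
    accuracy (percent of nominal) is reported per level, averaging
    replicate calibrators within a level; levels outside +/-15%
    (+/-20% at the lowest level) are flagged and excluded from the
    usable range.
    """
    if weighting not in _WEIGHTS:
        raise ValueError(f"unknown weighting {weighting!r}; use one of {sorted(_WEIGHTS)}")
    cal = [m for m in calibrators if m.role == "calibrator"]
    conc = np.array([m.nominal_conc for m in cal], dtype=float)
    if len(set(conc.tolist())) < 6:
        raise ValueError(
            f"calibration requires >= 6 distinct levels, got {len(set(conc.tolist()))}"
        )
    response = np.array([normalize(m) for m in cal])
    weights = _WEIGHTS[weighting](conc)
    model = sm.WLS(response, sm.add_constant(conc), weights=weights).fit()
    intercept, slope = model.params

    levels = sorted(set(conc.tolist()))
    lloq_level = levels[0]
    accuracies: dict[float, float] = {}
    failing: list[float] = []
    for level in levels:
        back = (response[conc == level].mean() - intercept) / slope
        acc = 100.0 * back / level
        accuracies[level] = acc
        tol = CAL_TOLERANCE_LLOQ_PCT if level == lloq_level else CAL_TOLERANCE_PCT
        if abs(acc - 100.0) > tol:
            failing.append(level)
    passing = [lv for lv in levels if lv not in failing]
    usable = (min(passing), max(passing)) if passing else (math.nan, math.nan)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        weighting_label=weighting,
        level_back_accuracies=accuracies,
        failing_levels=tuple(failing),
        usable_range=usable,
    )


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated concentration with range flags."""

    conc: float  # ug/mL
    flags: tuple[str, ...] = ()


def back_calculate(curve: CalibrationCurve, measurement: MrmMeasurement) -> BackCalcResult:
    """Invert the calibration line for one measurement.

    Negative back-calculations clamp to 0 with a ``below_zero`` flag so
    validation tables can still aggregate; values outside the usable range
    are flagged ``below_range`` / ``above_range``.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (normalize(measurement) - curve.intercept) / curve.slope
    flags: list[str] = []
    if conc < 0:
        conc = 0.0
        flags.append("below_zero")
    low, high = curve.usable_range
    if not math.isnan(low):
        if conc < low:
            flags.append("below_range")
        elif conc > high:
            flags.append("above_range")
    return BackCalcResult(conc=conc, flags=tuple(flags))


@dataclass(frozen=True)
class VariantContent:
    """Heterogeneity result for one N-terminal variant peptide."""

    label: str
    percent_of_max: float | None  # None = not detected
    share_pct: float | None

    @property
    def detected(self) -> bool:
        return self.percent_of_max is not None


def heterogeneity_content(
    variant_responses: Mapping[str, float | None],
) -> list[VariantContent]:
    """Variant content relative to the most abundant variant.

    ``variant_responses`` maps variant label to ISTD-normalized intensity;
    ``None`` marks a not-detected variant.  The most abundant variant is
    scaled to 100; shares are percent of the detected-variant total and sum
    to 100.  Values are reported at 3 significant figures.
    """
    if len(variant_responses) < 2:
        raise ValueError("heterogeneity requires at least 2 variants")
    detected = {k: v for k, v in variant_responses.items() if v is not None}
    total = sum(detected.values())
    if not detected or total <= 0:
        raise ValueError("all variant intensities are zero or not detected")
    top = max(detected.values())
    out = []
    for label, value in variant_responses.items():
        if value is None:
            out.append(VariantContent(label, None, None))
        else:
            out.append(
                VariantContent(
                    label,
                    round_sigfig(100.0 * value / top),
                    round_sigfig(100.0 * value / total),
                )
            )
    return out


@dataclass(frozen=True)
class OxidationRatio:
    """Monomer/dimer content of one condition, percent of its reference."""

    condition: str
    monomer_pct: float | None  # percent of reference condition; None = N.D.
    dimer_pct: float | None


def oxidation_ratio(
    conditions: Mapping[str, tuple[float | None, float | None]],
    monomer_reference: str,
    dimer_reference: str,
) -> list[OxidationRatio]:
    """Express monomer and dimer responses as percent of reference conditions.

    ``conditions`` maps condition label to ``(monomer, dimer)``
    ISTD-normalized intensities, ``None`` marking a not-detected species.
    The monomer reference condition (typically the untreated control) and
    the dimer reference (typically the fully oxidized sample) are each
    assigned 100; not-detected species propagate as ``None``, distinct
    from a measured zero.  Reported at 3 significant figures.
    """
    if monomer_reference not in conditions:
        raise ValueError(f"missing monomer reference condition {monomer_reference!r}")
    if dimer_reference not in conditions:
        raise ValueError(f"missing dimer reference condition {dimer_reference!r}")
    mono_ref = conditions[monomer_reference][0]
    if mono_ref is None or mono_ref <= 0:
        raise ValueError("monomer reference intensity must be positive")
    dimer_ref = conditions[dimer_reference][1]
    out = []
    for label, (mono, dimer) in conditions.items():
        mono_pct = None if mono is None else round_sigfig(100.0 * mono / mono_ref)
        if dimer is None or dimer_ref is None or dimer_ref <= 0:
            dimer_pct = None
        else:
            dimer_pct = round_sigfig(100.0 * dimer / dimer_ref)
        out.append(OxidationRatio(label, mono_pct, dimer_pct))
    return out
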