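"""Synthetic MRM peak-area generator for pipeline testing.

Emulates the output of a triple-quadrupole LC-MS run at the peak-area
level (chromatogram integration is upstream of this package): every
sample carries an analyte area and an internal-standard (ISTD) area, and
the expected ISTD-normalized response is linear in concentration,

    analyte_area = istd_area * (slope * c + intercept) * eps,

with ``eps`` lognormal multiplicative noise parameterized by a
coefficient of variation (lognormal keeps areas positive and makes the
CV the natural noise unit).  Blanks draw both channels from a small
background-noise distribution; zero samples carry ISTD but no analyte.

The default configuration reproduces a serum-validation study design:
a 10-point 2-fold calibration series from 100 ug/mL (lowest level
0.195 ug/mL), QC levels 0.195/0.586/9.38/80.0 ug/mL measured as 3 runs
of 5 replicates, an N-terminal variant trio, and monomer/dimer oxidation
conditions.  Per-measurement CVs default to 5-12%, largest near the
LLOQ where counting noise dominates.

All generators are pure functions of their configuration: the same seed
gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .quant import MrmMeasurement, serial_dilution_levels
from .validation import ETANERCEPT_QC, QcDesign


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int | None = None):
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for the synthetic generator.

    ``calibration_cv_pct`` maps calibration level index (0 = lowest) to a
    per-measurement CV; unlisted levels use ``default_cv_pct``.  The
    heterogeneity weights are true variant shares (sum 1); oxidation
    states are true monomer fractions per condition, scaled by
    ``oxidation_intensity`` relative to the control condition.
    """

    seed: int = 0
    slope: float = 0.02  # normalized response per ug/mL
    intercept: float = 0.0
    calibration_top: float = 100.0  # ug/mL
    calibration_levels: int = 10
    calibration_fold: float = 2.0
    qc_design: QcDesign = ETANERCEPT_QC
    qc_cv_pct: Mapping[str, float] = field(
        default_factory=lambda: {"LLOQ": 10.0, "LQC": 8.0, "MQC": 6.0, "HQC": 5.0}
    )
    calibration_cv_pct: Mapping[int, float] = field(
        default_factory=lambda: {0: 12.0, 1: 8.0}
    )
    default_cv_pct: float = 5.0
    istd_mean_area: float = 1.0e5
    istd_cv_pct: float = 5.0
    blank_noise_area: float = 50.0
    heterogeneity_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "MHVAQPAVVLASSR": 0.705,
            "AMHVAQPAVVLASSR": 0.261,
            "MAMHVAQPAVVLASSR": 0.034,
        }
    )
    heterogeneity_response: float = 1.0  # common response factor (shared y4)
    heterogeneity_cv_pct: float = 5.0
    oxidation_states: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # condition -> (monomer fraction, relative total intensity)
            "control": (1.0, 1.0),
            "H2O2": (0.00255, 1.0),
            "nSMOL solution": (0.956, 1.0),
            "Tris pH 8.0": (0.816, 1.0),
        }
    )
    oxidation_cv_pct: float = 5.0
    nd_threshold: float = 1.0e-4  # normalized response below which N.D.

    def __post_init__(self) -> None:
        total = sum(self.heterogeneity_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"heterogeneity weights must sum to 1, got {total}")
        for label, (fraction, _) in self.oxidation_states.items():
            if not 0.0 <= fraction <= 1.0:
                raise ValueError(
                    f"monomer fraction of condition {label!r} outside [0, 1]"
                )

    def calibration_concs(self) -> list[float]:
        """Calibration concentrations, lowest first."""
        return sorted(
            serial_dilution_levels(
                self.calibration_top, self.calibration_levels, self.calibration_fold
            )
        )


def _istd_area(config: SimulationConfig, rng: np.random.Generator) -> float:
    return config.istd_mean_area * float(
        _lognormal_factor(rng, config.istd_cv_pct / 100.0)
    )


def _measurement_at(
    config: SimulationConfig,
    rng: np.random.Generator,
    conc: float,
    cv_pct: float,
    **kwargs,
) -> MrmMeasurement:
    istd = _istd_area(config, rng)
    expected = config.slope * conc + config.intercept
    analyte = istd * expected * float(_lognormal_factor(rng, cv_pct / 100.0))
    return MrmMeasurement(analyte_area=analyte, istd_area=istd, **kwargs)


def simulate_peak_areas(config: SimulationConfig) -> list[MrmMeasurement]:
    """One full validation run set: blanks, zeros, calibrators, QC replicates.

    Calibrators are generated once (one injection per level, lowest level
    noisiest); QC samples follow the configured design of runs x
    replicates at each level.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    out: list[MrmMeasurement] = []
    for i in range(2):
        out.append(
            MrmMeasurement(
                sample_id=f"blank-{i + 1}",
                role="blank",
                transition_label="quantifier",
                analyte_area=config.blank_noise_area * float(rng.random()),
                istd_area=max(config.blank_noise_area * float(rng.random()), 1e-6),
                run_id="run1",
                replicate=i + 1,
            )
        )
        out.append(
            MrmMeasurement(
                sample_id=f"zero-{i + 1}",
                role="zero",
                transition_label="quantifier",
                analyte_area=config.blank_noise_area * float(rng.random()),
                istd_area=_istd_area(config, rng),
                run_id="run1",
                replicate=i + 1,
            )
        )
    for idx, conc in enumerate(config.calibration_concs()):
        cv = config.calibration_cv_pct.get(idx, config.default_cv_pct)
        out.append(
            _measurement_at(
                config,
                rng,
                conc,
                cv,
                sample_id=f"cal-{idx + 1}",
                role="calibrator",
                transition_label="quantifier",
                nominal_conc=conc,
                run_id="run1",
            )
        )
    design = config.qc_design
    for run in range(1, design.runs + 1):
        for level, conc in design.levels.items():
            cv = config.qc_cv_pct.get(level, config.default_cv_pct)
            for rep in range(1, design.replicates_per_run + 1):
                out.append(
                    _measurement_at(
                        config,
                        rng,
                        conc,
                        cv,
                        sample_id=f"qc-{level}-r{run}-{rep}",
                        role="qc",
                        transition_label="quantifier",
                        nominal_conc=conc,
                        run_id=f"run{run}",
                        replicate=rep,
                    )
                )
    return out


def simulate_heterogeneity(config: SimulationConfig) -> dict[str, float | None]:
    """Variant-label -> ISTD-normalized intensity for the N-terminal trio.

    Intensities are proportional to the true shares times a common
    response factor (the variants share their quantifier y-fragment, so a
    single factor is physically reasonable); variants falling below
    ``nd_threshold`` report ``None`` (not detected).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out: dict[str, float | None] = {}
    for label, share in config.heterogeneity_weights.items():
        value = (
            share
            * config.heterogeneity_response
            * float(_lognormal_factor(rng, config.heterogeneity_cv_pct / 100.0))
        )
        out[label] = None if value < config.nd_threshold else value
    return out


def simulate_oxidation(
    config: SimulationConfig,
) -> dict[str, tuple[float | None, float | None]]:
    """Condition -> (monomer, dimer) ISTD-normalized intensities.

    Each condition splits its total intensity between the reduced monomer
    and the disulfide dimer according to its true monomer fraction;
    species below ``nd_threshold`` report ``None`` (not detected).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out: dict[str, tuple[float | None, float | None]] = {}
    for label, (fraction, intensity) in config.oxidation_states.items():
        noise = _lognormal_factor(rng, config.oxidation_cv_pct / 100.0, size=2)
        monomer = fraction * intensity * float(noise[0])
        dimer = (1.0 - fraction) * intensity * float(noise[1])
        out[label] = (
            None if monomer < config.nd_threshold else monomer,
            None if dimer < config.nd_threshold else dimer,
        )
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
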