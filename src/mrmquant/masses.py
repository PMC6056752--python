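"""Exact monoisotopic mass and m/z arithmetic for MRM transition design.

Peptide masses are sums of monoisotopic residue masses plus one water;
protonated species follow ``(M + z * m_proton) / z``.  The b/y fragment
series are the N- and C-terminal backbone fragments produced by
collision-induced dissociation::

    b_i = (sum of first i residues + z * proton) / z
    y_i = (sum of last  i residues + water + z * proton) / z

Disulfide-bridged homodimers (the oxidized form of a cysteine-containing
peptide) lose two hydrogen atoms on bridge formation; a fragment released
by in-source disulfide cleavage retains the dehydro form and is one
hydrogen atom lighter than the reduced fragment.

All reported m/z values are computed monoisotopic values.  Vendor MRM
method tables often carry instrument-nominal values tuned on the machine;
:func:`match_transition` links such observed Q1/Q3 pairs back to computed
transitions and reports the deviation instead of adopting the printed
number as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

from ._rounding import round_half_away

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565  # Da, monoisotopic H2O
PROTON = 1.007276  # Da, H+
HYDROGEN_ATOM = 1.007825  # Da, neutral H


class MassError(ValueError):
    """Raised for residues or charges the mass model cannot handle."""


def _residue_sum(peptide: str) -> float:
    total = 0.0
    for pos, residue in enumerate(peptide, start=1):
        try:
            total += RESIDUE_MASSES[residue]
        except KeyError:
            raise MassError(
                f"unknown residue {residue!r} at position {pos} of {peptide!r}"
            ) from None
    return total


def monoisotopic_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of a peptide in Da."""
    if not peptide:
        raise MassError("empty peptide")
    return _residue_sum(peptide) + WATER


def precursor_mz(peptide: str, charge: int) -> float:
    """m/z of the ``[M + zH]z+`` precursor ion."""
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(peptide) + charge * PROTON) / charge


def fragment_mz(
    peptide: str, series: Literal["b", "y"], index: int, charge: int = 1
) -> float:
    """m/z of the ``b_i`` or ``y_i`` backbone fragment at the given charge."""
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    if not 1 <= index < len(peptide):
        raise MassError(
            f"fragment index {index} out of range for {len(peptide)}-residue peptide"
        )
    if series == "b":
        neutral = _residue_sum(peptide[:index])
    elif series == "y":
        neutral = _residue_sum(peptide[-index:]) + WATER
    else:
        raise MassError(f"unknown fragment series {series!r}")
    return (neutral + charge * PROTON) / charge


def disulfide_dimer_species(peptide: str) -> tuple[float, float, float]:
    """Masses of the oxidized disulfide-bridged homodimer of a Cys peptide.

    Returns ``(dimer neutral mass, dimer precursor m/z at charge 3,
    dehydro y-fragment m/z)`` where the y fragment is the full C-terminal
    fragment released on disulfide cleavage (y_{n-1} here), one hydrogen
    atom lighter than its reduced counterpart.

    The peptide must contain exactly one cysteine.
    """
    n_cys = peptide.count("C")
    if n_cys != 1:
        raise MassError(
            f"disulfide dimer requires exactly one cysteine, {peptide!r} has {n_cys}"
        )
    monomer = monoisotopic_mass(peptide)
    dimer = 2 * monomer - 2 * HYDROGEN_ATOM
    dimer_mz3 = (dimer + 3 * PROTON) / 3
    dehydro_y = fragment_mz(peptide, "y", len(peptide) - 1, 1) - HYDROGEN_ATOM
    return dimer, dimer_mz3, dehydro_y


@dataclass(frozen=True)
class TransitionSpec:
    """One MRM transition: a precursor (Q1) / fragment (Q3) m/z pair.

    ``role`` distinguishes the transition used for quantitation from those
    monitored only for structural confirmation.  ``instrument_meta`` carries
    opaque instrument settings (Q1/collision/Q3 voltages); they are stored
    verbatim and never computed.
    """

    peptide: str
    precursor_charge: int
    precursor_mz: float
    fragment_series: Literal["b", "y", "precursor-dimer"]
    fragment_index: int
    fragment_charge: int
    fragment_mz: float
    role: Literal["quantitation", "structure"] = "structure"
    instrument_meta: dict[str, Any] = field(default_factory=dict, compare=False)

    @property
    def label(self) -> str:
        charge_mark = "+" * self.fragment_charge
        return (
            f"{round_half_away(self.precursor_mz, 1)}->"
            f"{round_half_away(self.fragment_mz, 1)} "
            f"({self.fragment_series}{self.fragment_index}{charge_mark})"
        )


def build_transition_table(
    peptide: str,
    precursor_charges: Sequence[int] = (2,),
    fragment_series: Sequence[str] = ("y",),
    fragment_charges: Sequence[int] = (1,),
    n_quantitation: int = 1,
) -> list[TransitionSpec]:
    """Enumerate candidate MRM transitions for a peptide.

    All requested series/charge combinations are produced, highest fragment
    index first within each series.  The leading ``n_quantitation``
    transitions (by default the single highest-index y ion) carry the
    quantitation role and the remainder the structure role, mirroring the
    common one-quantifier-plus-qualifiers MRM design.
    """
    transitions: list[TransitionSpec] = []
    for z_pre in precursor_charges:
        pre = precursor_mz(peptide, z_pre)
        for series in fragment_series:
            for z_frag in fragment_charges:
                for index in range(len(peptide) - 1, 0, -1):
                    transitions.append(
                        TransitionSpec(
                            peptide=peptide,
                            precursor_charge=z_pre,
                            precursor_mz=pre,
                            fragment_series=series,  # type: ignore[arg-type]
                            fragment_index=index,
                            fragment_charge=z_frag,
                            fragment_mz=fragment_mz(peptide, series, index, z_frag),
                        )
                    )
    # Quantifier first, then qualifiers; any remaining enumerated fragments
    # keep the structure role so nothing is silently dropped.
    roles = [
        "quantitation" if i < n_quantitation else "structure"
        for i in range(len(transitions))
    ]
    return [
        TransitionSpec(
            peptide=t.peptide,
            precursor_charge=t.precursor_charge,
            precursor_mz=t.precursor_mz,
            fragment_series=t.fragment_series,
            fragment_index=t.fragment_index,
            fragment_charge=t.fragment_charge,
            fragment_mz=t.fragment_mz,
            role=role,  # type: ignore[arg-type]
        )
        for t, role in zip(transitions, roles)
    ]


@dataclass(frozen=True)
class TransitionMatch:
    """Result of matching an observed Q1/Q3 pair against a transition table."""

    transition: TransitionSpec
    delta_q1: float
    delta_q3: float

    @property
    def deviation(self) -> float:
        return max(abs(self.delta_q1), abs(self.delta_q3))


def match_transition(
    observed_q1: float,
    observed_q3: float,
    table: Sequence[TransitionSpec],
    tolerance: float = 0.5,
) -> TransitionMatch | None:
    """Nearest computed transition within ``tolerance`` Th, or ``None``.

    Distance is the Chebyshev deviation ``max(|dQ1|, |dQ3|)``; ties break
    on smaller combined deviation, then lower fragment index.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    best: TransitionMatch | None = None
    best_key: tuple[float, float, int] | None = None
    for t in table:
        d1 = observed_q1 - t.precursor_mz
        d3 = observed_q3 - t.fragment_mz
        dev = max(abs(d1), abs(d3))
        if dev > tolerance:
            continue
        key = (dev, abs(d1) + abs(d3), t.fragment_index)
        if best_key is None or key < best_key:
            best_key = key
            best = TransitionMatch(transition=t, delta_q1=d1, delta_q3=d3)
    return best
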