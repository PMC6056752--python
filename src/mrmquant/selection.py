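"""Signature-peptide candidate selection for protein LC-MS quantitation.

A surrogate ("signature") peptide stands in for the intact therapeutic in
an MRM assay, so the ideal candidate is 8-15 residues long, cysteine-free,
produced without missed cleavages, far from disulfide bridges, absent from
background proteins (endogenous IgG framework, the Fc portion shared by
all Fc-fusion drugs), and not at either protein terminus where ragged ends
create heterogeneity.  Fc-fusion proteins frequently leave no peptide that
satisfies every rule; candidates are therefore never discarded — each one
is reported with the explicit list of criteria it violates, and ranking
puts the least-violating, longest, most N-terminal peptides first.

Uniqueness screening collapses isoleucine and leucine to one symbol
because their residues are isobaric and MRM cannot tell them apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .proteins import TherapeuticProtein, TrypticPeptide, digest

#: Criterion labels used in violation lists.
LENGTH_BELOW_MIN = "length_below_min"
LENGTH_ABOVE_MAX = "length_above_max"
CONTAINS_CYSTEINE = "contains_cysteine"
MISSED_CLEAVAGE = "missed_cleavage"
NEAR_DISULFIDE = "near_disulfide"
PROTEIN_TERMINAL = "protein_terminal"
NOT_UNIQUE = "not_unique"


@dataclass(frozen=True)
class SelectionCriteria:
    """Tunable signature-peptide selection rules.

    ``disulfide_window`` is the residue distance below which a peptide
    counts as "in the vicinity" of a disulfide-bonded cysteine; the value
    is a primary-sequence distance, not a structural one.
    """

    min_len: int = 8
    max_len: int = 15
    forbid_cys: bool = True
    forbid_missed_cleavage: bool = True
    disulfide_window: int = 3
    forbid_terminal: bool = True
    require_unique: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.disulfide_window < 0:
            raise ValueError("disulfide_window must be non-negative")


@dataclass(frozen=True)
class CandidateReport:
    """One candidate peptide with its violation list and rank."""

    peptide: TrypticPeptide
    violations: tuple[str, ...]
    unique: bool
    rank: int

    @property
    def passes(self) -> bool:
        return not self.violations


def collapse_isobaric(sequence: str) -> str:
    """Replace I and L by a common symbol (J) for isobaric comparison."""
    return sequence.replace("I", "J").replace("L", "J")


def background_peptide_set(proteins: Sequence[TherapeuticProtein]) -> set[str]:
    """Union of fully-cleaved tryptic peptides of the background proteins.

    Peptides are stored I/L-collapsed; compare candidates through
    :func:`collapse_isobaric`.
    """
    if not proteins:
        raise ValueError("background requires at least one protein")
    background: set[str] = set()
    for protein in proteins:
        for peptide in digest(protein, max_missed=0):
            background.add(collapse_isobaric(peptide.sequence))
    return background


def fc_background(
    proteins: Iterable[TherapeuticProtein],
) -> list[TherapeuticProtein]:
    """Fc/framework portions (at and after the fusion junction) as background.

    Proteins without a fusion junction annotation are passed through whole.
    """
    out = []
    for protein in proteins:
        if protein.fusion_junction is None:
            out.append(protein)
        else:
            out.append(
                TherapeuticProtein(
                    id=f"{protein.id}:Fc",
                    name=f"{protein.name} Fc portion",
                    sequence=protein.sequence[protein.fusion_junction - 1 :],
                )
            )
    return out


def _violations(
    peptide: TrypticPeptide,
    criteria: SelectionCriteria,
    background: set[str] | None,
) -> tuple[tuple[str, ...], bool]:
    violations: list[str] = []
    if len(peptide) < criteria.min_len:
        violations.append(LENGTH_BELOW_MIN)
    if len(peptide) > criteria.max_len:
        violations.append(LENGTH_ABOVE_MAX)
    if criteria.forbid_cys and peptide.contains_cys:
        violations.append(CONTAINS_CYSTEINE)
    if criteria.forbid_missed_cleavage and peptide.missed_cleavages > 0:
        violations.append(MISSED_CLEAVAGE)
    if peptide.min_cys_distance < criteria.disulfide_window:
        violations.append(NEAR_DISULFIDE)
    if criteria.forbid_terminal and (peptide.is_n_terminal or peptide.is_c_terminal):
        violations.append(PROTEIN_TERMINAL)
    unique = True
    if background is not None:
        unique = collapse_isobaric(peptide.sequence) not in background
    if criteria.require_unique and not unique:
        violations.append(NOT_UNIQUE)
    return tuple(violations), unique


def select_candidates(
    protein: TherapeuticProtein,
    criteria: SelectionCriteria = SelectionCriteria(),
    background: set[str] | None = None,
    max_missed: int | None = None,
) -> list[CandidateReport]:
    """Rank every tryptic peptide of ``protein`` as a signature candidate.

    Nothing is dropped: each peptide appears exactly once with the list of
    enabled criteria it fails.  Ordering is fewest violations first, then
    longer peptides first, then N-to-C position.  ``max_missed`` defaults
    to 0 when missed cleavages are forbidden, else 2.
    """
    if max_missed is None:
        max_missed = 0 if criteria.forbid_missed_cleavage else 2
    reports = []
    for peptide in digest(protein, max_missed=max_missed):
        violations, unique = _violations(peptide, criteria, background)
        reports.append((peptide, violations, unique))
    reports.sort(key=lambda r: (len(r[1]), -len(r[0]), r[0].start))
    return [
        CandidateReport(peptide=p, violations=v, unique=u, rank=i + 1)
        for i, (p, v, u) in enumerate(reports)
    ]
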