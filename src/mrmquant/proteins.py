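"""Therapeutic protein sequences and in-silico tryptic digestion.

A therapeutic Fc-fusion protein is represented as an annotated amino-acid
sequence: which cysteines sit in disulfide bridges, where the fused Fc
domain begins, and which alternative N-terminal starts have been reported
for the product.  Trypsin cleaves C-terminal to lysine (K) or arginine (R)
except when the next residue is proline; :func:`digest` enumerates the
resulting peptides up to a chosen number of missed cleavages and annotates
each with everything the signature-peptide selection rules need.

Coordinates are 1-based inclusive throughout, matching the ``aa. 42-46``
style used in method documentation; :func:`to_zero_based` converts at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for residue codes outside the 20 standard amino acids."""


def _check_sequence(sequence: str, *, context: str = "sequence") -> None:
    if not sequence:
        raise SequenceError(f"{context} is empty")
    for pos, residue in enumerate(sequence, start=1):
        if residue not in STANDARD_RESIDUES:
            raise SequenceError(
                f"non-standard residue {residue!r} at position {pos} of {context}"
            )


@dataclass(frozen=True)
class TherapeuticProtein:
    """An annotated therapeutic protein sequence.

    Parameters
    ----------
    id : str
        Short record label (e.g. a FASTA id).
    name : str
        Free-text name.
    sequence : str
        Upper-case single-letter amino-acid codes.
    disulfide_cys_positions : tuple of int
        1-based indices of cysteines annotated as disulfide-bonded.
    fusion_junction : int or None
        1-based index of the first residue of the fused Fc domain.
    alternative_starts : tuple of (str, str)
        ``(label, prefix)`` pairs describing reported N-terminal variants;
        an empty prefix denotes the canonical start.
    """

    id: str
    name: str = ""
    sequence: str = ""
    disulfide_cys_positions: tuple[int, ...] = ()
    fusion_junction: int | None = None
    alternative_starts: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, context=f"protein {self.id!r}")
        object.__setattr__(
            self, "disulfide_cys_positions", tuple(self.disulfide_cys_positions)
        )
        object.__setattr__(
            self,
            "alternative_starts",
            tuple((str(a), str(b)) for a, b in self.alternative_starts),
        )
        for pos in self.disulfide_cys_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"disulfide position {pos} outside protein {self.id!r}"
                )
            if self.sequence[pos - 1] != "C":
                raise ValueError(
                    f"disulfide position {pos} of protein {self.id!r} is "
                    f"{self.sequence[pos - 1]!r}, not cysteine"
                )
        if self.fusion_junction is not None and not (
            1 <= self.fusion_junction <= len(self.sequence)
        ):
            raise ValueError(
                f"fusion junction {self.fusion_junction} outside protein {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrypticPeptide:
    """One tryptic digestion product with selection-relevant annotations."""

    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    is_n_terminal: bool = False
    is_c_terminal: bool = False
    contains_cys: bool = False
    min_cys_distance: int = 0
    parent_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}-{self.end} inconsistent with "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str) -> list[int]:
    """1-based positions after which trypsin cuts (K/R not followed by P)."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    return sites


def _min_cys_distance(
    start: int, end: int, cys_positions: tuple[int, ...]
) -> int | None:
    """Residue distance from the peptide to the nearest annotated cysteine.

    0 when the peptide itself spans an annotated cysteine; ``None`` when the
    parent has no annotated cysteines at all (treated as infinitely far).
    """
    if not cys_positions:
        return None
    best: int | None = None
    for pos in cys_positions:
        if start <= pos <= end:
            return 0
        d = start - pos if pos < start else pos - end
        if best is None or d < best:
            best = d
    return best


def digest(protein: TherapeuticProtein, max_missed: int = 2) -> list[TrypticPeptide]:
    """Enumerate tryptic peptides with 0..``max_missed`` missed cleavages.

    Peptides are returned ordered by start position, then by missed-cleavage
    count; at ``max_missed=0`` they partition the parent sequence exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    seq = protein.sequence
    sites = cleavage_sites(seq)
    # Fragment boundaries: 0-based half-open spans between consecutive sites.
    bounds = [0] + sites + [len(seq)]
    peptides: list[TrypticPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            lo, hi = bounds[i], bounds[j + 1]
            start, end = lo + 1, hi
            dist = _min_cys_distance(start, end, protein.disulfide_cys_positions)
            peptides.append(
                TrypticPeptide(
                    sequence=seq[lo:hi],
                    start=start,
                    end=end,
                    missed_cleavages=j - i,
                    is_n_terminal=start == 1,
                    is_c_terminal=end == len(seq),
                    contains_cys="C" in seq[lo:hi],
                    min_cys_distance=len(seq) if dist is None else dist,
                    parent_id=protein.id,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def enumerate_start_variants(protein: TherapeuticProtein) -> list[TrypticPeptide]:
    """First tryptic peptide of each reported N-terminal start variant.

    Each variant prefix is prepended to the parent sequence and the variant
    digested; the resulting N-terminal peptide is returned (coordinates in
    the variant's own frame).  An empty prefix yields the parent's own first
    peptide.  Used for N-terminal heterogeneity panels such as the
    MHVAQ... / AMHVAQ... / MAMHVAQ... trio of Abatacept.
    """
    if not protein.alternative_starts:
        raise ValueError(
            f"protein {protein.id!r} declares no alternative N-terminal starts"
        )
    out: list[TrypticPeptide] = []
    for label, prefix in protein.alternative_starts:
        if prefix:
            _check_sequence(prefix, context=f"variant {label!r} prefix")
        variant = TherapeuticProtein(
            id=f"{protein.id}:{label}" if label else protein.id,
            name=label or protein.name,
            sequence=prefix + protein.sequence,
        )
        out.append(digest(variant, max_missed=0)[0])
    return out


def to_zero_based(peptide: TrypticPeptide) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to a 0-based half-open span."""
    return peptide.start - 1, peptide.end
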