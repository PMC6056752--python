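"""File formats: FASTA sequences, sidecar annotations, peak-area CSV.

Sequences travel as plain FASTA; the annotations FASTA cannot carry
(disulfide cysteine positions, fusion junction, alternative N-terminal
starts) live in a YAML sidecar keyed by FASTA record id.  Peak areas use
a CSV dialect with an explicit header::

    sample_id,run_id,replicate,role,transition_label,analyte_area,istd_area,nominal_conc

Areas are arbitrary intensity units; concentrations are ug/mL.  Role is
one of blank/zero/calibrator/qc/unknown; calibrator and qc rows require
a nominal concentration, blank and zero rows leave it empty.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .proteins import STANDARD_RESIDUES, SequenceError, TherapeuticProtein
from .quant import MrmMeasurement

PEAK_AREA_COLUMNS = [
    "sample_id",
    "run_id",
    "replicate",
    "role",
    "transition_label",
    "analyte_area",
    "istd_area",
    "nominal_conc",
]

_ROLES = {"blank", "zero", "calibrator", "qc", "unknown"}

_ANNOTATION_KEYS = {
    "name",
    "disulfide_cys_positions",
    "fusion_junction",
    "alternative_starts",
}


def read_fasta(
    path: str | Path, annotations: dict | None = None
) -> list[TherapeuticProtein]:
    """Read protein records from FASTA, merging sidecar annotations by id.

    Lowercase residues are normalized to uppercase; gap or stop symbols
    (or any non-standard code) are rejected with the record named.
    Record order is preserved.
    """
    annotations = annotations or {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    proteins = []
    for record in records:
        sequence = str(record.seq).upper()
        bad = [c for c in set(sequence) if c not in STANDARD_RESIDUES]
        if bad:
            raise SequenceError(
                f"record {record.id!r}: non-standard symbols {sorted(bad)}"
            )
        meta = dict(annotations.get(record.id, {}))
        unknown = set(meta) - _ANNOTATION_KEYS
        if unknown:
            raise ValueError(
                f"unknown annotation keys for record {record.id!r}: {sorted(unknown)}; "
                f"expected a subset of {sorted(_ANNOTATION_KEYS)}"
            )
        proteins.append(
            TherapeuticProtein(
                id=record.id,
                name=meta.get("name", record.description),
                sequence=sequence,
                disulfide_cys_positions=tuple(meta.get("disulfide_cys_positions", ())),
                fusion_junction=meta.get("fusion_junction"),
                alternative_starts=tuple(
                    (str(label), str(prefix))
                    for label, prefix in meta.get("alternative_starts", ())
                ),
            )
        )
    return proteins


def write_fasta(proteins: Iterable[TherapeuticProtein], path: str | Path) -> None:
    with open(path, "w") as handle:
        for protein in proteins:
            handle.write(f">{protein.id} {protein.name}\n")
            for i in range(0, len(protein.sequence), 60):
                handle.write(protein.sequence[i : i + 60] + "\n")


def read_annotations(path: str | Path) -> dict:
    """Load the YAML annotation sidecar (record id -> annotation mapping)."""
    with open(path) as handle:
        loaded = yaml.safe_load(handle) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"annotation file {path} must map record ids to annotations")
    return loaded


def read_peak_areas(path: str | Path | _stdio.IOBase) -> list[MrmMeasurement]:
    """Read MRM peak-area measurements from CSV.

    Validates the header, the role vocabulary, area signs, and the
    calibrator/qc nominal-concentration requirement; errors name the
    offending row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PEAK_AREA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"peak-area CSV missing columns: {missing}")
    measurements = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        role = str(row.role)
        if role not in _ROLES:
            raise ValueError(
                f"row {idx}: unknown role {role!r}; expected one of {sorted(_ROLES)}"
            )
        nominal = None if pd.isna(row.nominal_conc) else float(row.nominal_conc)
        try:
            measurements.append(
                MrmMeasurement(
                    sample_id=str(row.sample_id),
                    role=role,  # type: ignore[arg-type]
                    transition_label=str(row.transition_label),
                    analyte_area=float(row.analyte_area),
                    istd_area=float(row.istd_area),
                    nominal_conc=nominal,
                    run_id=str(row.run_id),
                    replicate=int(row.replicate),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return measurements


def write_peak_areas(
    measurements: Sequence[MrmMeasurement], path: str | Path | _stdio.IOBase
) -> None:
    """Write measurements in the peak-area CSV dialect (round-trips)."""
    frame = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "run_id": m.run_id,
                "replicate": m.replicate,
                "role": m.role,
                "transition_label": m.transition_label,
                "analyte_area": m.analyte_area,
                "istd_area": m.istd_area,
                "nominal_conc": m.nominal_conc,
            }
            for m in measurements
        ],
        columns=PEAK_AREA_COLUMNS,
    )
    # %.17g round-trips IEEE doubles exactly through text
    frame.to_csv(path, index=False, float_format="%.17g")
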