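"""Bundled reference constants and synthetic demonstration sequences.

The calibrant peptide sequences and the two signature peptides are real,
published sequences.  The full-length "toy" therapeutic sequences are
SYNTHETIC stand-ins: short invented Fc-fusion-like constructs that place
the real signature peptides at realistic tryptic contexts (VFCTK at
aa 42-46 of the Etanercept-like toy; MHVAQPAVVLASSR at aa 1-14 of the
Abatacept-like toy) and share an immunoglobulin-Fc-like tail so that the
background uniqueness screen has something to screen against.  They are
NOT the licensed products' sequences and exist only so every pipeline
stage runs without downloads.
"""

from __future__ import annotations

from .proteins import TherapeuticProtein

#: External MALDI calibrants (singly protonated monoisotopic species).
BRADYKININ_1_7 = "RPPGFSP"
ANGIOTENSIN_II = "DRVYIHPF"
#: Internal-standard peptide: fourteen prolines and one C-terminal arginine.
P14R = "PPPPPPPPPPPPPPR"

#: Signature peptides used for quantitation of the two Fc-fusion drugs.
SIGNATURE_ETANERCEPT = "VFCTK"
SIGNATURE_ABATACEPT = "MHVAQPAVVLASSR"

#: Synthetic immunoglobulin-Fc-like tail shared by the toy constructs.
_FC_TAIL = (
    "THTCPPCPAPELLGGPSVFLFPPKPK"
    "DTLMISR"
    "TPEVTCVVVDVSHEDPEVK"
    "FNWYVDGVEVHNAK"
)

#: Synthetic Etanercept-like toy: receptor-like N-portion (with VFCTK at
#: aa 42-46 and a dense disulfide-cysteine context) fused to the Fc tail.
ETANERCEPT_TOY = TherapeuticProtein(
    id="ETN-toy",
    name="synthetic Etanercept-like Fc-fusion construct",
    sequence=(
        "LPAQVAFTPYAPEPGSTCR"  # 1-19
        "YIHPQNNSIC"  # 20-29
        "CTKCHKGTYL"  # 30-39
        "HR"  # 40-41
        "VFCTK"  # 42-46
        "CSPGFGVAR"  # 47-55
        + _FC_TAIL  # 56-
    ),
    disulfide_cys_positions=(18, 29, 30, 33, 44, 47),
    fusion_junction=56,
)

#: Synthetic Abatacept-like toy: CTLA-4-like N-portion starting with the
#: signature peptide, fused to the Fc tail, with the three reported
#: N-terminal start variants.
ABATACEPT_TOY = TherapeuticProtein(
    id="ABT-toy",
    name="synthetic Abatacept-like Fc-fusion construct",
    sequence=(
        "MHVAQPAVVLASSR"  # 1-14
        "GIASFVCEYASPGK"  # 15-28
        "ATEVR"  # 29-33
        "VTVLR"  # 34-38
        "QADSQVTEVCAK"  # 39-50
        + _FC_TAIL  # 51-
    ),
    disulfide_cys_positions=(21, 48),
    fusion_junction=51,
    alternative_starts=(
        ("canonical", ""),
        ("ala-extended", "A"),
        ("met-ala-extended", "MA"),
    ),
)

#: Synthetic endogenous-IgG-like background protein sharing the Fc tail.
BACKGROUND_IGG_TOY = TherapeuticProtein(
    id="IgG-toy",
    name="synthetic endogenous IgG-like background",
    sequence="EVQLVESGGGLVQPGGSLRLSCAASGFTFSK" + _FC_TAIL,
)
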