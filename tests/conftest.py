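import pytest

from mrmquant.data import ABATACEPT_TOY, BACKGROUND_IGG_TOY, ETANERCEPT_TOY
from mrmquant.simulate import SimulationConfig


@pytest.fixture
def etanercept_toy():
    return ETANERCEPT_TOY


@pytest.fixture
def abatacept_toy():
    return ABATACEPT_TOY


@pytest.fixture
def background_igg():
    return BACKGROUND_IGG_TOY


@pytest.fixture
def noise_free_config():
    """Generator configuration with every noise source switched off."""
    return SimulationConfig(
        seed=0,
        qc_cv_pct={"LLOQ": 0.0, "LQC": 0.0, "MQC": 0.0, "HQC": 0.0},
        calibration_cv_pct={},
        default_cv_pct=0.0,
        istd_cv_pct=0.0,
        heterogeneity_cv_pct=0.0,
        oxidation_cv_pct=0.0,
    )


def brute_force_digest(sequence: str, max_missed: int):
    """Independent digestion oracle: test every substring directly.

    A substring is a tryptic peptide iff both of its boundaries are valid
    cleavage boundaries (sequence ends, or after K/R not followed by P)
    and it spans at most ``max_missed`` internal cleavage sites.
    Returns (sequence, start, end, missed) tuples with 1-based inclusive
    coordinates.
    """

    def boundary(i: int) -> bool:  # 0-based position between residues
        if i == 0 or i == len(sequence):
            return True
        return sequence[i - 1] in "KR" and sequence[i] != "P"

    out = []
    for lo in range(len(sequence)):
        for hi in range(lo + 1, len(sequence) + 1):
            if not (boundary(lo) and boundary(hi)):
                continue
            internal = sum(1 for k in range(lo + 1, hi) if boundary(k))
            if internal <= max_missed:
                out.append((sequence[lo:hi], lo + 1, hi, internal))
    return out
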