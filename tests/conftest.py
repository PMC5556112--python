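import numpy as np
import pytest

from pudti import SyntheticSpec, generate

# PSI-BLAST -out_ascii_pssm dialect, 4 positions; synthetic golden file
PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts\n"
    "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F"
    "   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I"
    "   L   K   M   F   P   S   T   W   Y   V\n"
)

#: 4 x 20 log-odds block of the golden file (row-major)
PSSM_SCORES = np.array(
    [
        [-1, -2, -3, -4, -2, 0, -3, -3, -2, 1, 2, -2, 8, 0, -3, -2, -1, -2, -1, 1],
        [5, -2, -2, -2, -1, -1, -1, 0, -2, -2, -2, -1, -1, -3, -1, 1, 0, -3, -2, 0],
        [-2, 6, -1, -2, -4, 1, 0, -3, 0, -3, -3, 2, -2, -3, -2, -1, -1, -3, -2, -3],
        [-2, -2, 6, 1, -3, 0, 0, -1, 1, -4, -4, 0, -3, -3, -2, 1, 0, -4, -2, -3],
    ],
    dtype=float,
)

PSSM_RESIDUES = "MARN"


def pssm_text(scores: np.ndarray = PSSM_SCORES, residues: str = PSSM_RESIDUES,
              n_score_cols: int = 20) -> str:
    lines = [PSSM_HEADER]
    pct = np.zeros(20, dtype=int)
    for i, (res, row) in enumerate(zip(residues, scores), start=1):
        body = "  ".join(f"{int(v):3d}" for v in row[:n_score_cols])
        if n_score_cols >= 20:
            pcts = "  ".join(f"{v:3d}" for v in pct)
            lines.append(f"{i:5d} {res}   {body}  {pcts}  0.50 0.25\n")
        else:
            lines.append(f"{i:5d} {res}   {body}\n")
    lines.append("\n                      K         Lambda\n")
    lines.append("Standard Ungapped    0.1377     0.3164\n")
    return "".join(lines)


@pytest.fixture
def pssm_file(tmp_path):
    path = tmp_path / "prot.pssm"
    path.write_text(pssm_text())
    return path


@pytest.fixture(scope="session")
def small_planted():
    """Small dataset with a clear planted signal, for pipeline-level tests."""
    spec = SyntheticSpec(
        n_drugs=80, n_targets=12, n_features=40, n_informative=12,
        positive_rate=0.12, label_rate=0.6, effect_size=1.5, seed=101,
    )
    return generate(spec)
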