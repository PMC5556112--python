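"""Per-interaction feature vectors from drug and protein descriptors.

Each drug-target pair is described by the concatenation ``F = [G; O; A; B]``:

- ``G`` — ingested drug descriptors (e.g. 1444 PaDEL columns),
- ``O`` — binary protein-domain indicator over a fixed vocabulary
  (1331 human PFAM domains at the published scale),
- ``A`` — Chou's type-I pseudo amino acid composition, 20 + lambda
  entries (lambda = 30 -> 50),
- ``B`` — 400 bi-gram features of the protein's position-specific
  scoring matrix.

At the published scale this yields a 1781-dimensional protein block and a
3225-dimensional pair vector.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Canonical property tables of type-I pseudo amino acid composition:
# hydrophobicity, hydrophilicity and side-chain mass, in AMINO_ACIDS order.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def _standardized_properties() -> np.ndarray:
    """3 x 20 property matrix, each row zero-mean unit-variance over residues."""
    rows = []
    for table in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDE_CHAIN_MASS):
        vals = np.array([table[a] for a in AMINO_ACIDS])
        rows.append((vals - vals.mean()) / vals.std())
    return np.vstack(rows)


_PROPS = _standardized_properties()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def build_domain_vector(
    annotations: list[str], vocabulary: list[str]
) -> np.ndarray:
    """Binary indicator of a protein's domains over an ordered vocabulary.

    Annotations outside the vocabulary are ignored with a logged warning;
    the operation is deliberately permissive.
    """
    if not vocabulary:
        raise ValueError("domain vocabulary is empty")
    if len(set(vocabulary)) != len(vocabulary):
        raise ValueError("domain vocabulary ids must be unique")
    index = {d: i for i, d in enumerate(vocabulary)}
    vec = np.zeros(len(vocabulary))
    unknown = []
    for dom in annotations:
        if dom in index:
            vec[index[dom]] = 1.0
        else:
            unknown.append(dom)
    if unknown:
        logger.warning("domains outside the vocabulary ignored: %s", unknown)
    return vec


def compute_paac(
    sequence: str, lam: int = 30, weight: float = 0.05
) -> np.ndarray:
    """Chou's type-I pseudo amino acid composition.

    The first 20 entries are proportional to residue frequencies; the last
    ``lam`` entries are proportional to ``weight * theta_k``, where theta_k
    averages squared property differences between residues k positions
    apart over hydrophobicity, hydrophilicity and side-chain mass (each
    standardized over the 20 residues). The whole vector is normalized to
    sum to 1.
    """
    seq = sequence.upper()
    length = len(seq)
    if length <= lam:
        raise ValueError(
            f"sequence too short for lambda: length {length} <= lambda {lam}"
        )
    for pos, aa in enumerate(seq):
        if aa not in _AA_INDEX:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos + 1}"
            )
    idx = np.array([_AA_INDEX[a] for a in seq])
    freq = np.bincount(idx, minlength=20) / length

    props = _PROPS[:, idx]  # 3 x L
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diff = props[:, k:] - props[:, :-k]
        # correlation factor: mean over pairs of the mean squared
        # property difference
        thetas[k - 1] = np.mean(np.mean(diff**2, axis=0))

    denom = freq.sum() + weight * thetas.sum()
    return np.concatenate([freq, weight * thetas]) / denom


def sigmoid_transform(pssm: np.ndarray) -> np.ndarray:
    """Squash log-odds scores into (0, 1) with the logistic function."""
    return 1.0 / (1.0 + np.exp(-np.asarray(pssm, dtype=float)))


def bigram_transition(T: np.ndarray) -> np.ndarray:
    """Bi-gram matrix B[i, j] = sum_k T[k, i] * T[k+1, j], flattened row-major.

    Bilinear in T: scaling T by a scales B by a**2.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[1] != 20:
        raise ValueError(f"expected an L x 20 matrix, got shape {T.shape}")
    if T.shape[0] < 2:
        raise ValueError("PSSM must have at least 2 positions for bi-grams")
    return (T[:-1].T @ T[1:]).ravel()


def compute_bigram_pssm(
    pssm: np.ndarray, transform: str = "sigmoid"
) -> np.ndarray:
    """400-dimensional bi-gram descriptor of a PSSM.

    ``transform='sigmoid'`` (default) squashes raw log-odds into (0, 1)
    before the bi-gram sum; ``'none'`` uses the matrix as given.
    """
    pssm = np.asarray(pssm, dtype=float)
    if transform == "sigmoid":
        T = sigmoid_transform(pssm)
    elif transform == "none":
        T = pssm
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return bigram_transition(T)


def assemble_protein_vector(
    O: np.ndarray, A: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Protein block Q = [O; A; B] (1781-d at the published scale)."""
    return np.concatenate([O, A, B])


def assemble_dti_vector(
    G: np.ndarray,
    O: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    expected_lengths: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Pair vector F = [G; O; A; B] in that fixed order.

    ``expected_lengths`` optionally enforces the dataset-wide layout
    (d_G, |vocabulary|, 20 + lambda, 400); a mismatch is an error.
    """
    parts = [np.asarray(v, dtype=float).ravel() for v in (G, O, A, B)]
    if expected_lengths is not None:
        actual = tuple(len(p) for p in parts)
        if actual != tuple(expected_lengths):
            raise ValueError(
                f"component lengths {actual} do not match configured "
                f"layout {tuple(expected_lengths)}"
            )
    return np.concatenate(parts)
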