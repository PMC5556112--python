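"""Readers and writers for the external formats of the pipeline.

Canonical pair format is TSV with a header row; labels are serialized as
``1`` (known interaction) and ``0`` (unlabeled). Predicted negatives appear
as ``-1`` only in output files, never on input: negatives are what the
tool produces, not what it consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: PSI-BLAST column order of the 20 standard residues.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

POSITIVE = 1
UNLABELED = 0


@dataclass
class PairTable:
    """Drug-target pair list with PU labels (1 positive, 0 unlabeled)."""

    drug_ids: list[str]
    target_ids: list[str]
    labels: np.ndarray  # int array, values in {1, 0}

    def __len__(self) -> int:
        return len(self.drug_ids)

    @property
    def pair_ids(self) -> list[str]:
        return [f"{d}::{t}" for d, t in zip(self.drug_ids, self.target_ids)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": self.drug_ids,
                "target_id": self.target_ids,
                "label": self.labels,
            }
        )


@dataclass
class FeatureTable:
    """Dense sample-by-feature matrix with aligned ids and feature names."""

    sample_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but "
                f"{self.matrix.shape[0]} matrix rows"
            )
        if not self.feature_names:
            self.feature_names = [
                f"f_{i + 1:04d}" for i in range(self.matrix.shape[1])
            ]
        if len(self.feature_names) != self.matrix.shape[1]:
            raise ValueError("feature name count does not match matrix width")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains missing/non-finite values")


def read_pairs(path: str | Path) -> PairTable:
    """Read a TSV pair list (drug_id, target_id[, label]).

    A missing label column defaults every pair to unlabeled. Duplicate
    (drug, target) pairs and unknown label tokens are errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty pair file: %s", path)
        return PairTable([], [], np.zeros(0, dtype=int))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pair file needs >= 2 columns")
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["drug_id", "target_id", "label"]))
    )
    if len(df) == 0:
        logger.warning("pair file has a header but no rows: %s", path)
        return PairTable([], [], np.zeros(0, dtype=int))
    dup = df.duplicated(subset=["drug_id", "target_id"])
    if dup.any():
        pairs = df.loc[dup, ["drug_id", "target_id"]].apply(tuple, axis=1)
        raise ValueError(f"duplicate pairs in {path}: {sorted(set(pairs))}")
    if "label" in df.columns:
        tokens = df["label"].fillna("0").str.strip()
        bad = sorted(set(tokens) - {"0", "1"})
        if bad:
            raise ValueError(f"unknown label tokens in {path}: {bad}")
        labels = tokens.astype(int).to_numpy()
    else:
        labels = np.zeros(len(df), dtype=int)
    return PairTable(
        list(df["drug_id"]), list(df["target_id"]), labels.astype(int)
    )


def write_pairs(table: PairTable, path: str | Path) -> None:
    """Write a pair table sorted by (drug_id, target_id)."""
    df = table.to_frame().sort_values(["drug_id", "target_id"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV/TSV feature table whose first column is the sample id."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in feature table")
    return FeatureTable(
        [str(i) for i in df.index],
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(
        table.matrix, index=table.sample_ids, columns=table.feature_names
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_pssm(path: str | Path) -> np.ndarray:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 matrix.

    Only the first 20 score columns (position-specific log-odds, residue
    order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V) are kept; the weighted
    percentage block and trailing statistics are ignored. Scores are
    returned unchanged (negative log-odds are not clipped).
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            # body rows start "<pos> <residue> <20 ints> [...]"
            if len(parts) < 2 or not parts[0].isdigit():
                continue
            if parts[1].upper() not in PSSM_ALPHABET:
                continue
            scores = parts[2:]
            numeric: list[float] = []
            for tok in scores:
                try:
                    numeric.append(float(tok))
                except ValueError:
                    break
            if len(numeric) < 20:
                raise ValueError(
                    f"{path}: PSSM row {parts[0]} has {len(numeric)} score "
                    "columns, expected 20"
                )
            rows.append(numeric[:20])
    if not rows:
        raise ValueError(f"{path}: no PSSM body rows found (truncated file?)")
    return np.array(rows, dtype=float)


def read_domain_annotations(path: str | Path) -> dict[str, list[str]]:
    """Read 'protein_id<TAB>domain;domain;...' annotation lists."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            pid = fields[0]
            doms = []
            if len(fields) > 1 and fields[1]:
                doms = [d for d in fields[1].replace(",", ";").split(";") if d]
            out[pid] = doms
    return out


def read_domain_vocabulary(path: str | Path) -> list[str]:
    """Read the ordered domain vocabulary, one accession per line."""
    vocab: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                vocab.append(line)
    if len(vocab) != len(set(vocab)):
        raise ValueError(f"{path}: duplicate ids in domain vocabulary")
    return vocab
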