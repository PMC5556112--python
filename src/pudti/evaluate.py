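"""Metrics and the repeated pairwise cross-validation protocol.

Evaluation masks drug-target *pairs* (not whole drugs or targets):
each trial partitions all pairs into ``folds`` roughly equal subsets,
holds one out with its labels masked, rebuilds the PU split inside the
training portion (``r`` percent of known interactions form P, everything
else joins the unlabeled pool U) and runs the full pipeline. Masked known
interactions count as positives and masked unlabeled pairs as negatives
when scoring, the gold-standard convention in this literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .config import RunConfig
from .pipeline import fit_pudti, fit_random_baseline

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F-measure; zero denominators give 0."""
    if counts.tp + counts.fp == 0:
        logger.warning("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        logger.warning("no positive labels; recall defined as 0")
        recall = 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes among the labels")
    return float(roc_auc_score(labels, scores))


def random_negative_baseline(
    u_idx: np.ndarray, size: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Uniform sample without replacement from the unlabeled pool."""
    u_idx = np.asarray(u_idx)
    if size > u_idx.size:
        raise ValueError(f"requested {size} negatives from |U| = {u_idx.size}")
    rng = np.random.default_rng(seed)
    return rng.choice(u_idx, size=size, replace=False)


@dataclass
class CVReport:
    """Per-(trial, fold) metrics and their aggregates."""

    records: pd.DataFrame  # columns: trial, fold, precision, recall, f, auc
    #: test-fold index arrays in evaluation order, for leakage audits
    fold_test_indices: list = field(default_factory=list)

    @property
    def means(self) -> pd.Series:
        return self.records[["precision", "recall", "f", "auc"]].mean()

    @property
    def stds(self) -> pd.Series:
        return self.records[["precision", "recall", "f", "auc"]].std(ddof=0)

    def summary(self) -> dict:
        return {
            "mean": self.means.to_dict(),
            "std": self.stds.to_dict(),
            "n_evaluations": int(len(self.records)),
        }


def _partition(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def pairwise_cv(
    X: np.ndarray,
    known: np.ndarray,
    config: RunConfig | None = None,
    folds: int | None = None,
    trials: int | None = None,
    r: float | None = None,
    seed: int | None = None,
    baseline: str = "none",
) -> CVReport:
    """Repeated pairwise cross-validation of the full pipeline.

    ``known`` flags the pairs whose interaction is known (the PU
    positives). ``baseline='random'`` swaps the consensus extractor for
    uniform random negative selection, all else equal.
    """
    config = config or RunConfig()
    folds = folds or config.folds
    trials = trials or config.trials
    r = r if r is not None else config.r
    seed = seed if seed is not None else config.seed
    if folds < 2:
        raise ValueError("cross-validation needs folds >= 2")
    if baseline not in ("none", "random"):
        raise ValueError(f"unknown baseline {baseline!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    known = np.asarray(known).astype(bool)
    n = X.shape[0]
    if known.sum() < folds:
        raise ValueError("dataset must contain at least `folds` positives")
    rng = np.random.default_rng(seed)

    fit = fit_random_baseline if baseline == "random" else fit_pudti
    rows = []
    fold_test_indices: list[np.ndarray] = []
    for trial in range(trials):
        parts = _partition(n, folds, rng)
        for fold, test_idx in enumerate(parts):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            # leakage guard: masked pairs never reach a training stage
            assert np.intersect1d(train_idx, test_idx).size == 0
            fold_test_indices.append(test_idx)
            train_known = train_idx[known[train_idx]]
            if train_known.size == 0:
                raise ValueError(
                    f"trial {trial} fold {fold}: training split has no "
                    "known positives"
                )
            n_p = max(1, int(round(r / 100 * train_known.size)))
            p_idx = rng.choice(train_known, size=n_p, replace=False)
            u_idx = np.setdiff1d(train_idx, p_idx)
            model = fit(X, p_idx, u_idx, config=config, seed=rng)

            scores = model.decision_function(X[test_idx])
            y_true = known[test_idx].astype(int)
            y_pred = (scores > 0).astype(int)
            counts = ConfusionCounts(
                tp=int(((y_pred == 1) & (y_true == 1)).sum()),
                fp=int(((y_pred == 1) & (y_true == 0)).sum()),
                tn=int(((y_pred == 0) & (y_true == 0)).sum()),
                fn=int(((y_pred == 0) & (y_true == 1)).sum()),
            )
            precision, recall, f = prf(counts)
            rows.append(
                {
                    "trial": trial,
                    "fold": fold,
                    "precision": precision,
                    "recall": recall,
                    "f": f,
                    "auc": auc(scores, y_true),
                }
            )
    return CVReport(
        records=pd.DataFrame(rows), fold_test_indices=fold_test_indices
    )
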