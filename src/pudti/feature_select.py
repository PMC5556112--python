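"""Discriminant-ability feature selection between P and the unlabeled pool.

Each feature f receives an association count in the positive set P and in
the unlabeled set U (how many samples "have" the feature), and a
discriminant ability score

    da(f) = (as(f,P) + as(f,U)) * ln(|P|/as(f,P) + |U|/as(f,U)),

which is large when the feature is frequent in one set but rare in the
other. The top-k features by da are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: continuity correction replacing zero counts inside the log ratios
ZERO_COUNT_SMOOTHING = 0.5


@dataclass
class BinarizePolicy:
    """Presence rule for Eq.-style association on mixed feature types.

    Columns whose observed values are a subset of {0, 1} are treated as
    already-binary indicators (present iff value == 1). Other columns are
    binarized by a per-feature threshold computed once over P ∪ U:
    ``median`` -> present iff value strictly exceeds the column median;
    ``nonzero`` -> present iff value != 0.
    """

    mode: str = "median"
    thresholds: np.ndarray | None = None  # per-feature, NaN for binary cols
    is_binary: np.ndarray | None = None

    @classmethod
    def fit(cls, X: np.ndarray, mode: str = "median") -> "BinarizePolicy":
        if mode not in ("median", "nonzero"):
            raise ValueError(f"unknown binarize mode {mode!r}")
        X = np.asarray(X, dtype=float)
        is_binary = np.array(
            [np.isin(np.unique(col), (0.0, 1.0)).all() for col in X.T]
        )
        thresholds = np.full(X.shape[1], np.nan)
        if mode == "median":
            thresholds[~is_binary] = np.median(X[:, ~is_binary], axis=0)
        else:
            thresholds[~is_binary] = 0.0
        return cls(mode=mode, thresholds=thresholds, is_binary=is_binary)

    def associate(self, X: np.ndarray) -> np.ndarray:
        """0/1 presence matrix under the fitted policy."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros_like(X)
        out[:, self.is_binary] = (X[:, self.is_binary] > 0.5).astype(float)
        cont = ~self.is_binary
        if self.mode == "median":
            out[:, cont] = (X[:, cont] > self.thresholds[cont]).astype(float)
        else:
            out[:, cont] = (X[:, cont] != 0).astype(float)
        return out


def association_score(presence: np.ndarray) -> np.ndarray:
    """Per-feature count of samples having the feature in a sample set."""
    presence = np.atleast_2d(presence)
    if presence.shape[0] == 0:
        raise ValueError("association score over an empty sample set")
    return presence.sum(axis=0)


def discriminant_score(
    as_p: np.ndarray | float,
    as_u: np.ndarray | float,
    n_p: int,
    n_u: int,
) -> np.ndarray | float:
    """da(f) with natural log and 0.5 smoothing of zero counts."""
    as_p = np.asarray(as_p, dtype=float)
    as_u = np.asarray(as_u, dtype=float)
    safe_p = np.where(as_p == 0, ZERO_COUNT_SMOOTHING, as_p)
    safe_u = np.where(as_u == 0, ZERO_COUNT_SMOOTHING, as_u)
    da = (as_p + as_u) * np.log(n_p / safe_p + n_u / safe_u)
    return float(da) if da.ndim == 0 else da


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, descending; ties -> lower index first."""
    scores = np.asarray(scores, dtype=float)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > scores.size:
        raise ValueError(f"k={k} exceeds number of features {scores.size}")
    # stable sort on (-score, index): lexsort's last key is primary
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


@dataclass
class FeatureSelector:
    """Fitted selection: binarization policy, scores and kept indices."""

    policy: BinarizePolicy
    scores: np.ndarray
    selected: np.ndarray

    @classmethod
    def fit(
        cls,
        X_p: np.ndarray,
        X_u: np.ndarray,
        k: int,
        mode: str = "median",
    ) -> "FeatureSelector":
        X_p = np.atleast_2d(X_p)
        X_u = np.atleast_2d(X_u)
        policy = BinarizePolicy.fit(np.vstack([X_p, X_u]), mode=mode)
        as_p = association_score(policy.associate(X_p))
        as_u = association_score(policy.associate(X_u))
        scores = discriminant_score(as_p, as_u, X_p.shape[0], X_u.shape[0])
        k = min(k, X_p.shape[1])
        return cls(policy=policy, scores=scores, selected=select_top_k(scores, k))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X)[:, self.selected]
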