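"""Similarity weights for ambiguous samples.

Reliable negatives are partitioned into ``a`` k-means modules and each
module is paired with Rocchio-style positive/negative prototypes. An
ambiguous sample then receives

- a *local* weight pair: its k-means cluster is tagged member-by-member
  (temporarily positive iff the best positive-prototype cosine beats the
  best negative-prototype cosine) and every member shares the tag
  fractions (LocP, LocN);
- a *global* weight pair (GloP, GloN): its total cosine similarity to all
  positive prototypes normalized against the total over both prototype
  families;
- a combined pair W^P = (1-alpha) LocP + alpha GloP (same for W^N).

All three pairs sum to one per sample; the combined pair feeds the
weighted-slack SVM as soft class-membership probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .ndtise import cosine, rocchio_prototype

logger = logging.getLogger(__name__)

__all__ = [
    "PrototypeSet",
    "AmbiguousClustering",
    "cosine",
    "cluster_count",
    "compute_prototypes",
    "local_weights",
    "global_weights",
    "combine_weights",
    "similarity_weights",
]


@dataclass
class PrototypeSet:
    """Paired positive/negative prototypes, one pair per RN module."""

    positives: np.ndarray  # a x d
    negatives: np.ndarray  # a x d

    @property
    def a(self) -> int:
        return self.positives.shape[0]


@dataclass
class AmbiguousClustering:
    """k-means clusters over the ambiguous set with temporary tags."""

    labels: np.ndarray  # cluster index per ambiguous sample
    tags: np.ndarray  # +1/-1 temporary tag per sample
    n_clusters: int

    def tag_counts(self, cluster: int) -> tuple[int, int]:
        mask = self.labels == cluster
        pos = int((self.tags[mask] == 1).sum())
        return pos, int(mask.sum()) - pos


def cluster_count(t: int, part_size: int, total_size: int) -> int:
    """round(t * part / total), floored at 1 with a warning."""
    if total_size <= 0:
        raise ValueError("total size must be positive")
    k = int(round(t * part_size / total_size))
    if k < 1:
        logger.warning(
            "cluster count %d < 1 for t=%d, part=%d/%d; using 1",
            k, t, part_size, total_size,
        )
        k = 1
    return k


def _kmeans(X: np.ndarray, k: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    k = min(k, X.shape[0])
    km = KMeans(
        n_clusters=k,
        n_init=10,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return km.fit_predict(X)


def compute_prototypes(
    X_pos: np.ndarray,
    X_rn: np.ndarray,
    u_size: int,
    t: int = 30,
    alpha: float = 16.0,
    beta: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> PrototypeSet:
    """Cluster RN into ``a = round(t |RN| / (|U| + |RN|))`` modules and
    build one (p_i, n_i) Rocchio prototype pair per module.

    ``u_size`` is the size of the remaining unlabeled (ambiguous) pool,
    so the RN and ambiguous clusterings share the budget ``t``.
    """
    X_pos = np.atleast_2d(X_pos)
    X_rn = np.atleast_2d(X_rn)
    if X_pos.shape[0] == 0 or X_rn.shape[0] == 0:
        raise ValueError("prototype construction needs non-empty P and RN")
    a = cluster_count(t, X_rn.shape[0], u_size + X_rn.shape[0])
    labels = _kmeans(X_rn, a, seed)
    pos_list, neg_list = [], []
    for i in np.unique(labels):
        cluster = X_rn[labels == i]
        neg_list.append(rocchio_prototype(cluster, X_pos, alpha, beta))
        pos_list.append(rocchio_prototype(X_pos, cluster, alpha, beta))
    return PrototypeSet(
        positives=np.vstack(pos_list), negatives=np.vstack(neg_list)
    )


def _best_cosines(x: np.ndarray, prototypes: PrototypeSet) -> tuple[float, float]:
    best_p = max(cosine(x, p) for p in prototypes.positives)
    best_n = max(cosine(x, n) for n in prototypes.negatives)
    return best_p, best_n


def local_weights(
    X_amb: np.ndarray,
    prototypes: PrototypeSet,
    rn_size: int,
    t: int = 30,
    seed: int | np.random.Generator = 0,
    n_clusters: int | None = None,
) -> tuple[np.ndarray, AmbiguousClustering]:
    """Cluster-shared local weight pairs (LocP, LocN) per ambiguous sample.

    The ambiguous pool is split into ``n = round(t |A| / (|A| + |RN|))``
    k-means clusters (overridable via ``n_clusters``); each member is
    temporarily tagged positive iff its best positive-prototype cosine
    strictly beats its best negative-prototype cosine (ties tag negative),
    and all members of a cluster share (pos fraction, neg fraction).
    """
    X_amb = np.atleast_2d(X_amb)
    if X_amb.shape[0] == 0:
        raise ValueError("no ambiguous samples to weight")
    if n_clusters is None:
        n_clusters = cluster_count(t, X_amb.shape[0], X_amb.shape[0] + rn_size)
    labels = _kmeans(X_amb, n_clusters, seed)
    tags = np.empty(X_amb.shape[0], dtype=int)
    for i, x in enumerate(X_amb):
        bp, bn = _best_cosines(x, prototypes)
        tags[i] = 1 if bp > bn else -1
    clustering = AmbiguousClustering(
        labels=labels, tags=tags, n_clusters=len(np.unique(labels))
    )
    weights = np.empty((X_amb.shape[0], 2))
    for c in np.unique(labels):
        mask = labels == c
        pos, neg = clustering.tag_counts(c)
        size = pos + neg
        weights[mask] = (pos / size, neg / size)
    return weights, clustering


def global_weights(
    X_amb: np.ndarray, prototypes: PrototypeSet
) -> np.ndarray:
    """Per-sample (GloP, GloN) from summed prototype cosines.

    Cosines are floored at 0 so the weights stay in [0, 1]; a sample whose
    floored similarities all vanish gets the uninformative pair (0.5, 0.5).
    """
    X_amb = np.atleast_2d(X_amb)
    out = np.empty((X_amb.shape[0], 2))
    for i, x in enumerate(X_amb):
        sim_p = sum(max(cosine(x, p), 0.0) for p in prototypes.positives)
        sim_n = sum(max(cosine(x, n), 0.0) for n in prototypes.negatives)
        denom = sim_p + sim_n
        if denom <= 0:
            logger.warning(
                "sample %d has no positive similarity to any prototype; "
                "assigning (0.5, 0.5)", i,
            )
            out[i] = (0.5, 0.5)
        else:
            out[i] = (sim_p / denom, sim_n / denom)
    return out


def combine_weights(
    local: np.ndarray, glob: np.ndarray, alpha: float = 0.6
) -> np.ndarray:
    """W = (1 - alpha) * local + alpha * global, rowwise on (P, N) pairs."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"balance alpha must be in [0, 1], got {alpha}")
    return (1 - alpha) * np.asarray(local) + alpha * np.asarray(glob)


def similarity_weights(
    X_amb: np.ndarray,
    prototypes: PrototypeSet,
    rn_size: int,
    t: int = 30,
    alpha: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Local, global and combined weight pairs for the ambiguous set."""
    rng = np.random.default_rng(seed)
    loc, clustering = local_weights(
        X_amb, prototypes, rn_size=rn_size, t=t, seed=rng
    )
    glo = global_weights(X_amb, prototypes)
    comb = combine_weights(loc, glo, alpha=alpha)
    for name, w in (("local", loc), ("global", glo), ("combined", comb)):
        sums = w.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError(f"{name} weight pairs do not sum to 1")
    return {
        "local": loc,
        "global": glo,
        "combined": comb,
        "clustering": clustering,
    }
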