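"""End-to-end PU screening pipeline: select -> extract -> weight -> train."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .feature_select import FeatureSelector
from .ndtise import SampleSplit, ndtise
from .svm_sw import SVMSWModel, train_svm_sw
from .weighting import PrototypeSet, compute_prototypes, similarity_weights

logger = logging.getLogger(__name__)


@dataclass
class PUDTIModel:
    """Fitted pipeline: feature selector, sample split and SVM-SW model."""

    selector: FeatureSelector
    split: SampleSplit
    prototypes: PrototypeSet | None
    weights: np.ndarray | None
    svm: SVMSWModel
    config: RunConfig

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.selector.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.selector.transform(X))


def fit_pudti(
    X: np.ndarray,
    p_idx: np.ndarray,
    u_idx: np.ndarray,
    config: RunConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> PUDTIModel:
    """Run the full pipeline on positives ``p_idx`` vs unlabeled ``u_idx``.

    Stages: discriminant feature selection on (P, U); reliable-negative /
    extracted-positive / ambiguous consensus split; prototype construction
    on P ∪ EP vs clustered RN; similarity weighting of the ambiguous set;
    weighted-slack SVM training.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p_idx = np.asarray(p_idx, dtype=int)
    u_idx = np.asarray(u_idx, dtype=int)

    selector = FeatureSelector.fit(
        X[p_idx], X[u_idx], k=config.top_k, mode=config.binarize
    )
    Xs = selector.transform(X)

    split = ndtise(
        Xs,
        p_idx,
        u_idx,
        spy_ratio=config.spy_ratio,
        noise_percentile=config.spy_noise_percentile,
        rocchio_alpha=config.rocchio_alpha,
        rocchio_beta=config.rocchio_beta,
        seed=rng,
        spy_max_iter=config.spy_max_iter,
        spy_tol=config.spy_tol,
    )
    X_pos = Xs[split.positives_augmented]
    X_rn = Xs[split.RN]

    prototypes: PrototypeSet | None = None
    weights = None
    X_amb = None
    if len(split.A):
        X_amb = Xs[split.A]
        prototypes = compute_prototypes(
            X_pos,
            X_rn,
            u_size=len(split.A),
            t=config.t,
            alpha=config.rocchio_alpha,
            beta=config.rocchio_beta,
            seed=rng,
        )
        weights = similarity_weights(
            X_amb,
            prototypes,
            rn_size=len(split.RN),
            t=config.t,
            alpha=config.balance_alpha,
            seed=rng,
        )["combined"]

    svm = train_svm_sw(
        X_pos,
        X_rn,
        X_amb,
        weights,
        c1=config.c1,
        c2=config.c2,
        c3=config.c3,
        c4=config.c4,
        gamma=config.rbf_gamma,
    )
    return PUDTIModel(
        selector=selector,
        split=split,
        prototypes=prototypes,
        weights=weights,
        svm=svm,
        config=config,
    )


def fit_random_baseline(
    X: np.ndarray,
    p_idx: np.ndarray,
    u_idx: np.ndarray,
    config: RunConfig | None = None,
    seed: int | np.random.Generator | None = None,
    negative_ratio: float = 3.0,
) -> PUDTIModel:
    """Baseline pipeline: negatives drawn uniformly from the unlabeled pool.

    Mirrors the common practice the consensus extractor replaces: RN is a
    uniform sample of ``negative_ratio * |P|`` unlabeled pairs (capped at
    |U|), no ambiguous weighting, plain two-class SVM.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p_idx = np.asarray(p_idx, dtype=int)
    u_idx = np.asarray(u_idx, dtype=int)

    selector = FeatureSelector.fit(
        X[p_idx], X[u_idx], k=config.top_k, mode=config.binarize
    )
    Xs = selector.transform(X)
    size = min(len(u_idx), max(1, int(round(negative_ratio * len(p_idx)))))
    rn = rng.choice(u_idx, size=size, replace=False)
    rest = np.setdiff1d(u_idx, rn)
    split = SampleSplit(
        P=p_idx, U=u_idx, RN=rn, EP=np.empty(0, dtype=int), A=rest
    )
    svm = train_svm_sw(
        Xs[p_idx], Xs[rn], c1=config.c1, c4=config.c4, gamma=config.rbf_gamma
    )
    return PUDTIModel(
        selector=selector,
        split=split,
        prototypes=None,
        weights=None,
        svm=svm,
        config=config,
    )
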