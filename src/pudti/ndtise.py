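"""Reliable-negative extraction from unlabeled drug-target pairs (NDTISE).

Two classical PU learners are run on (P, U) and combined by consensus:

- a *spy* classifier — a fraction of P is planted into U as spies, a
  Gaussian naive Bayes model is refined by expectation-maximization over
  the unlabeled side, and the spies' posteriors calibrate the threshold
  below which a sample is called negative;
- a *Rocchio* classifier — class prototypes are weighted differences of
  normalized class centroids and samples are assigned by cosine.

A pair is a reliable negative (RN) only if both classifiers call it
negative; it is an extracted positive (EP) only if both call it positive;
everything else remains ambiguous (A). This AND-consensus trades recall
for precision, the property that matters when RN becomes the negative
training class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class SampleSplit:
    """Partition of the unlabeled pool produced by the consensus rule."""

    P: np.ndarray  # indices of original positives
    U: np.ndarray  # indices of original unlabeled samples
    RN: np.ndarray  # reliable negatives (subset of U)
    EP: np.ndarray  # extracted positives (subset of U)
    A: np.ndarray  # ambiguous remainder (subset of U)

    def __post_init__(self) -> None:
        rn, ep, a = set(self.RN), set(self.EP), set(self.A)
        if rn & ep or rn & a or ep & a:
            raise AssertionError("RN, EP, A must be disjoint")
        if rn | ep | a != set(self.U):
            raise AssertionError("RN ∪ EP ∪ A must cover U exactly")
        if set(self.P) & set(self.U):
            raise AssertionError("P and U must be disjoint")

    @property
    def positives_augmented(self) -> np.ndarray:
        """P ∪ EP, the positive set used by downstream prototype building."""
        return np.concatenate([self.P, self.EP]).astype(int)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes with soft responsibilities (for the spy EM loop)
# ---------------------------------------------------------------------------


class _SoftGaussianNB:
    """Per-feature Gaussian class model accepting fractional class weights."""

    def __init__(self, var_floor_scale: float = 1e-9):
        self.var_floor_scale = var_floor_scale

    def fit(self, X: np.ndarray, w_pos: np.ndarray, w_neg: np.ndarray):
        eps = 1e-12
        self.var_floor = self.var_floor_scale * max(X.var(), 1e-12)
        stats = []
        for w in (w_pos, w_neg):
            tot = w.sum() + eps
            mean = (w[:, None] * X).sum(axis=0) / tot
            var = (w[:, None] * (X - mean) ** 2).sum(axis=0) / tot
            stats.append((tot, mean, np.maximum(var, self.var_floor)))
        (self.n_pos, self.mu_pos, self.var_pos) = stats[0]
        (self.n_neg, self.mu_neg, self.var_neg) = stats[1]
        total = self.n_pos + self.n_neg
        self.log_prior_pos = np.log(self.n_pos / total)
        self.log_prior_neg = np.log(self.n_neg / total)
        return self

    def _log_joint(self, X: np.ndarray, mu, var, log_prior) -> np.ndarray:
        ll = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var)
        return ll.sum(axis=1) + log_prior

    def posterior_pos(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_joint(X, self.mu_pos, self.var_pos, self.log_prior_pos)
        ln = self._log_joint(X, self.mu_neg, self.var_neg, self.log_prior_neg)
        m = np.maximum(lp, ln)
        ep, en = np.exp(lp - m), np.exp(ln - m)
        return ep / (ep + en)


def spy_classify(
    X_p: np.ndarray,
    X_u: np.ndarray,
    spy_ratio: float = 0.15,
    noise_percentile: float = 5.0,
    seed: int | np.random.Generator = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> np.ndarray:
    """Spy-calibrated PU labels (+1/-1) for every unlabeled sample.

    A random ``ceil(spy_ratio * |P|)`` positives are planted into the
    unlabeled side; Gaussian naive Bayes posteriors are refined by EM over
    the unlabeled side's class responsibilities; the threshold is the
    ``noise_percentile``-th percentile of spy posteriors, and an unlabeled
    sample is negative iff its positive posterior falls below it.
    """
    rng = np.random.default_rng(seed)
    X_p = np.atleast_2d(np.asarray(X_p, dtype=float))
    X_u = np.atleast_2d(np.asarray(X_u, dtype=float))
    n_p = X_p.shape[0]
    if n_p < 10:
        raise ValueError(f"too few positives to spy: |P| = {n_p} < 10")
    n_spies = int(np.ceil(spy_ratio * n_p))
    if n_spies >= n_p:
        raise ValueError(
            f"spy_ratio {spy_ratio} leaves no positives (spies = {n_spies})"
        )
    spy_idx = rng.choice(n_p, size=n_spies, replace=False)
    keep = np.setdiff1d(np.arange(n_p), spy_idx)

    X_pos = X_p[keep]
    X_side = np.vstack([X_u, X_p[spy_idx]])  # unlabeled side incl. spies
    n_side = X_side.shape[0]

    X_all = np.vstack([X_pos, X_side])
    # responsibilities: labeled positives fixed at 1; unlabeled side starts 0
    resp = np.zeros(n_side)
    nb = _SoftGaussianNB()
    converged = False
    for _ in range(max_iter):
        w_pos = np.concatenate([np.ones(len(X_pos)), resp])
        w_neg = np.concatenate([np.zeros(len(X_pos)), 1.0 - resp])
        nb.fit(X_all, w_pos, w_neg)
        new_resp = nb.posterior_pos(X_side)
        if np.max(np.abs(new_resp - resp)) < tol:
            resp = new_resp
            converged = True
            break
        resp = new_resp
    if not converged:
        logger.warning(
            "spy EM did not converge after %d iterations; using last iterate",
            max_iter,
        )
    post_u = resp[: X_u.shape[0]]
    post_spy = resp[X_u.shape[0]:]
    th = np.percentile(post_spy, noise_percentile)
    return np.where(post_u < th, -1, 1)


def _normalized_mean(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # zero vectors contribute nothing directional
    return (X / norms).mean(axis=0)


def rocchio_prototype(
    X_own: np.ndarray, X_other: np.ndarray, alpha: float = 16.0, beta: float = 4.0
) -> np.ndarray:
    """alpha * mean of own normalized samples - beta * mean of the others."""
    return alpha * _normalized_mean(X_own) - beta * _normalized_mean(X_other)


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity; defined as 0 if either vector has zero norm."""
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def rocchio_classify(
    X_p: np.ndarray,
    X_u: np.ndarray,
    alpha: float = 16.0,
    beta: float = 4.0,
) -> np.ndarray:
    """Rocchio PU labels (+1/-1) for every unlabeled sample.

    c+ is built from P against U, c- from U against P; a sample is
    positive iff it is strictly more cosine-similar to c+ than to c-.
    """
    X_p = np.atleast_2d(np.asarray(X_p, dtype=float))
    X_u = np.atleast_2d(np.asarray(X_u, dtype=float))
    if X_p.shape[0] == 0 or X_u.shape[0] == 0:
        raise ValueError("Rocchio needs non-empty P and U")
    c_pos = rocchio_prototype(X_p, X_u, alpha, beta)
    c_neg = rocchio_prototype(X_u, X_p, alpha, beta)
    labels = np.empty(X_u.shape[0], dtype=int)
    for i, x in enumerate(X_u):
        labels[i] = 1 if cosine(x, c_pos) > cosine(x, c_neg) else -1
    return labels


def ndtise(
    X: np.ndarray,
    p_idx: np.ndarray,
    u_idx: np.ndarray,
    spy_ratio: float = 0.15,
    noise_percentile: float = 5.0,
    rocchio_alpha: float = 16.0,
    rocchio_beta: float = 4.0,
    seed: int | np.random.Generator = 0,
    spy_max_iter: int = 50,
    spy_tol: float = 1e-4,
) -> SampleSplit:
    """AND-consensus split of the unlabeled pool into RN, EP and A.

    RN = both classifiers negative; EP = both positive; A = disagreement.
    An empty RN is an error: downstream training requires a negative class
    (typically remedied by raising ``noise_percentile`` or checking that
    the features separate the classes at all).
    """
    p_idx = np.asarray(p_idx, dtype=int)
    u_idx = np.asarray(u_idx, dtype=int)
    if p_idx.size == 0 or u_idx.size == 0:
        raise ValueError("NDTISE needs non-empty P and U")
    X_p, X_u = X[p_idx], X[u_idx]
    c_spy = spy_classify(
        X_p,
        X_u,
        spy_ratio=spy_ratio,
        noise_percentile=noise_percentile,
        seed=seed,
        max_iter=spy_max_iter,
        tol=spy_tol,
    )
    c_roc = rocchio_classify(X_p, X_u, alpha=rocchio_alpha, beta=rocchio_beta)
    rn_mask = (c_spy == -1) & (c_roc == -1)
    ep_mask = (c_spy == 1) & (c_roc == 1)
    a_mask = ~(rn_mask | ep_mask)
    if not rn_mask.any():
        raise ValueError(
            "NDTISE extracted no reliable negatives; relax the spy "
            "noise percentile or revisit the feature representation"
        )
    return SampleSplit(
        P=p_idx,
        U=u_idx,
        RN=u_idx[rn_mask],
        EP=u_idx[ep_mask],
        A=u_idx[a_mask],
    )
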