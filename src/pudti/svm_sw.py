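"""Similarity-weighted soft-margin SVM (SVM-SW).

The classifier minimizes

    1/2 ||w||^2 + C1 Σ_{P} ε_i + C2 Σ_{A} W^P(x_j) ε_j
                + C3 Σ_{A} W^N(x_m) ε_m + C4 Σ_{RN} ε_n

subject to the usual margin constraints, where each ambiguous sample x is
constrained toward *both* classes with slack penalties scaled by its soft
class-membership weights W^P(x), W^N(x). The problem reduces exactly to a
per-sample-penalty C-SVM: positives enter once with penalty C1, reliable
negatives once with C4, and each ambiguous sample twice, as a positive row
with penalty C2*W^P(x) and a negative row with C3*W^N(x). In the dual each
row r carries its own box constraint 0 <= lambda_r <= c_r. With no
ambiguous samples and C1 = C4 = C the model is the standard C-SVM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: rows with smaller penalty are dropped — unpenalized slack makes their
#: margin constraint vacuous
PENALTY_EPS = 1e-12


@dataclass
class AugmentedTrainingSet:
    """Rows of (feature vector, role label y in {+1,-1}, slack penalty c)."""

    X: np.ndarray
    y: np.ndarray
    penalties: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        self.penalties = np.asarray(self.penalties, dtype=float)
        if not (len(self.X) == len(self.y) == len(self.penalties)):
            raise ValueError("augmented set arrays must have equal length")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("role labels must be +1/-1")
        if (self.penalties <= 0).any():
            raise ValueError("penalties must be positive")

    def __len__(self) -> int:
        return len(self.y)


def build_augmented_set(
    X_p: np.ndarray,
    X_rn: np.ndarray,
    X_amb: np.ndarray | None,
    weights: np.ndarray | None,
    c1: float = 1.0,
    c2: float = 1.0,
    c3: float = 1.0,
    c4: float = 1.0,
) -> AugmentedTrainingSet:
    """Expand (P, RN, ambiguous + weights) into per-row penalty rows.

    ``weights`` holds one (W^P, W^N) pair per ambiguous sample and must
    cover the ambiguous set exactly. Rows whose penalty falls below
    ``PENALTY_EPS`` are dropped.
    """
    X_p = np.atleast_2d(X_p)
    X_rn = np.atleast_2d(X_rn)
    blocks_X = [X_p, X_rn]
    blocks_y = [np.ones(len(X_p), dtype=int), -np.ones(len(X_rn), dtype=int)]
    blocks_c = [np.full(len(X_p), c1), np.full(len(X_rn), c4)]
    if X_amb is not None and len(X_amb):
        X_amb = np.atleast_2d(X_amb)
        weights = np.atleast_2d(weights) if weights is not None else None
        if weights is None or len(weights) != len(X_amb):
            raise ValueError(
                "every ambiguous sample needs a (W^P, W^N) weight pair"
            )
        blocks_X += [X_amb, X_amb]
        blocks_y += [
            np.ones(len(X_amb), dtype=int),
            -np.ones(len(X_amb), dtype=int),
        ]
        blocks_c += [c2 * weights[:, 0], c3 * weights[:, 1]]
    X = np.vstack(blocks_X)
    y = np.concatenate(blocks_y)
    c = np.concatenate(blocks_c)
    keep = c >= PENALTY_EPS
    return AugmentedTrainingSet(X=X[keep], y=y[keep], penalties=c[keep])


@dataclass
class SVMSWModel:
    """Trained kernel model: support rows, dual coefficients and bias.

    ``dual_coef[r] = y_r * lambda_r``; the decision score of x is
    ``sum_r dual_coef[r] * K(x_r, x) + b`` and the label is +1 iff the
    score is strictly positive.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    penalties: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    objective: float | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = rbf_kernel(X, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 iff the decision score is strictly positive (0 is negative)."""
        return np.where(self.decision_function(X) > 0, 1, -1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": "rbf",
                "gamma": self.gamma,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coef": self.dual_coef.tolist(),
                "intercept": self.intercept,
                "penalties": list(self.penalties),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SVMSWModel":
        d = json.loads(text)
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            penalties=tuple(d.get("penalties", (1.0, 1.0, 1.0, 1.0))),
        )


def primal_objective(
    aug: AugmentedTrainingSet, model: SVMSWModel
) -> float:
    """1/2 ||w||^2 + sum_r c_r * max(0, 1 - y_r f(x_r)) for a fitted model."""
    K_ss = rbf_kernel(
        model.support_vectors, model.support_vectors, gamma=model.gamma
    )
    w_sq = float(model.dual_coef @ K_ss @ model.dual_coef)
    scores = model.decision_function(aug.X)
    slack = np.maximum(0.0, 1.0 - aug.y * scores)
    return 0.5 * w_sq + float(aug.penalties @ slack)


def train(
    aug: AugmentedTrainingSet,
    gamma: float | None = None,
    tol: float = 1e-6,
) -> SVMSWModel:
    """Fit the per-row-penalty kernel SVM on an augmented training set.

    The dual with per-row box constraints ``0 <= lambda_r <= c_r`` is the
    standard C-SVM dual with per-sample weights, solved here with C fixed
    at 1 and each row's penalty supplied as its sample weight. The bias is
    the solver's margin-support-vector estimate.
    """
    classes = np.unique(aug.y)
    if classes.size < 2:
        raise ValueError("training set must contain both roles (+1 and -1)")
    if gamma is None:
        gamma = 1.0 / aug.X.shape[1]
    svc = SVC(C=1.0, kernel="rbf", gamma=gamma, tol=tol, shrinking=True)
    svc.fit(aug.X, aug.y, sample_weight=aug.penalties)
    if not svc.fit_status_ == 0:
        raise RuntimeError("SVM solver reported non-convergence")
    model = SVMSWModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(gamma),
    )
    model.objective = primal_objective(aug, model)
    return model


def train_svm_sw(
    X_p: np.ndarray,
    X_rn: np.ndarray,
    X_amb: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    c1: float = 1.0,
    c2: float = 1.0,
    c3: float = 1.0,
    c4: float = 1.0,
    gamma: float | None = None,
    tol: float = 1e-6,
) -> SVMSWModel:
    """Convenience wrapper: build the augmented set and train."""
    aug = build_augmented_set(X_p, X_rn, X_amb, weights, c1, c2, c3, c4)
    model = train(aug, gamma=gamma, tol=tol)
    model.penalties = (c1, c2, c3, c4)
    return model


def penalty_grid(
    min_exp: float = -5.0, max_exp: float = 5.0, step_exp: float = 0.5
) -> np.ndarray:
    """Powers of two over an exponent range, the documented search grid."""
    exps = np.arange(min_exp, max_exp + 1e-9, step_exp)
    return 2.0**exps

def grid_search(
    X_p: np.ndarray,
    X_rn: np.ndarray,
    X_amb: np.ndarray | None,
    weights: np.ndarray | None,
    c_grid: np.ndarray,
    gamma_grid: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    tie_penalties: bool = True,
) -> tuple[dict, float]:
    """Exhaustive search maximizing mean CV AUC over labeled rows.

    With ``tie_penalties`` (default) one value C is shared by C1..C4,
    keeping the search tractable; otherwise the full 4-D product of
    ``c_grid`` is scanned. Folds stratify P vs RN; ambiguous rows always
    stay in the training side. Ties prefer smaller penalties, then
    smaller gamma.
    """
    c_grid = np.sort(np.asarray(c_grid, dtype=float))
    gamma_grid = np.sort(np.asarray(gamma_grid, dtype=float))
    if c_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    X_p, X_rn = np.atleast_2d(X_p), np.atleast_2d(X_rn)
    X_lab = np.vstack([X_p, X_rn])
    y_lab = np.concatenate([np.ones(len(X_p)), -np.ones(len(X_rn))])
    folds = min(folds, len(X_p), len(X_rn))
    skf = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)

    if tie_penalties:
        combos = [(c, c, c, c) for c in c_grid]
    else:
        combos = list(product(c_grid, repeat=4))

    best: tuple[float, dict] | None = None
    for cs in combos:
        for gamma in gamma_grid:
            aucs = []
            for tr, te in skf.split(X_lab, y_lab):
                if len(np.unique(y_lab[te])) < 2:
                    continue
                model = train_svm_sw(
                    X_lab[tr][y_lab[tr] == 1],
                    X_lab[tr][y_lab[tr] == -1],
                    X_amb,
                    weights,
                    *cs,
                    gamma=gamma,
                )
                scores = model.decision_function(X_lab[te])
                aucs.append(roc_auc_score(y_lab[te], scores))
            mean_auc = float(np.mean(aucs)) if aucs else 0.0
            # strict > keeps the first (smallest penalties/gamma) maximizer
            if best is None or mean_auc > best[0] + 1e-12:
                best = (
                    mean_auc,
                    {
                        "c1": cs[0], "c2": cs[1], "c3": cs[2], "c4": cs[3],
                        "gamma": float(gamma),
                    },
                )
    return best[1], best[0]
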