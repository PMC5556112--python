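"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Parameters of the PU screening pipeline.

    Defaults follow the published settings where the method states them
    (``r=30``, ``top_k=300``, ``t=30``, ``rocchio_alpha=16``,
    ``rocchio_beta=4``, ``balance_alpha=0.6``, RBF kernel); the remaining
    knobs (spy ratio, noise percentile, penalty grids) are standard
    PU-learning defaults.

    Parameters
    ----------
    r : float
        Percent of known interactions forming the positive set P in the
        PU split of the evaluation protocol (0 < r <= 100).
    top_k : int
        Number of features kept by discriminant-ability selection.
    t : int
        Total cluster budget shared between reliable-negative clustering
        and ambiguous-sample clustering.
    rocchio_alpha, rocchio_beta : float
        Own-class and opposing-class weights of the Rocchio prototype.
    balance_alpha : float
        Mixing weight between global and local similarity weights
        (0 = purely local, 1 = purely global).
    spy_ratio : float
        Fraction of P planted into U as spies.
    spy_noise_percentile : float
        Percentile of spy posteriors used as the negative threshold.
    c1, c2, c3, c4 : float
        Slack penalties for P, ambiguous-as-positive, ambiguous-as-negative
        and RN rows of the weighted SVM.
    c_grid_min_exp, c_grid_max_exp, c_grid_step_exp : float
        Penalty grid is ``2**exp`` for exponents in
        [c_grid_min_exp, c_grid_max_exp] with the given exponent step.
    rbf_gamma : float or None
        RBF width; None means 1 / (number of selected features).
    folds, trials : int
        Cross-validation folds and repetitions.
    seed : int
        Master seed; every random stage derives its stream from it.
    """

    r: float = 30.0
    top_k: int = 300
    t: int = 30
    rocchio_alpha: float = 16.0
    rocchio_beta: float = 4.0
    balance_alpha: float = 0.6
    spy_ratio: float = 0.15
    spy_noise_percentile: float = 5.0
    spy_max_iter: int = 50
    spy_tol: float = 1e-4
    c1: float = 1.0
    c2: float = 1.0
    c3: float = 1.0
    c4: float = 1.0
    c_grid_min_exp: float = -5.0
    c_grid_max_exp: float = 5.0
    c_grid_step_exp: float = 0.5
    rbf_gamma: float | None = None
    binarize: str = "median"
    folds: int = 5
    trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r <= 100:
            raise ValueError(f"r must be in (0, 100], got {self.r}")
        if not 0 <= self.balance_alpha <= 1:
            raise ValueError(
                f"balance_alpha must be in [0, 1], got {self.balance_alpha}"
            )
        for name in ("c1", "c2", "c3", "c4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0 < self.spy_ratio < 1:
            raise ValueError("spy_ratio must be in (0, 1)")
        if self.binarize not in ("median", "nonzero"):
            raise ValueError("binarize must be 'median' or 'nonzero'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
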