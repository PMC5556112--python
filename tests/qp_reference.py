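"""Generic convex-QP reference solution of the weighted SVM dual.

Independent of the package's training path: the dual

    max  sum(lam) - 1/2 lam' (yy' * K) lam
    s.t. 0 <= lam_r <= c_r,   lam'y = 0

is handed to scipy's SLSQP as a black-box constrained program. Used only
as an oracle in tests.
"""

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics.pairwise import rbf_kernel


def solve_weighted_svm_qp(X, y, c, gamma):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    K = rbf_kernel(X, X, gamma=gamma)
    Q = (y[:, None] * y[None, :]) * K
    n = len(y)

    res = minimize(
        lambda lam: 0.5 * lam @ Q @ lam - lam.sum(),
        np.zeros(n),
        jac=lambda lam: Q @ lam - 1.0,
        bounds=[(0.0, ci) for ci in c],
        constraints=[{"type": "eq", "fun": lambda l: l @ y, "jac": lambda l: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    lam = res.x

    def decision(Z):
        return (lam * y) @ rbf_kernel(X, np.atleast_2d(Z), gamma=gamma)

    free = (lam > 1e-7 * c) & (lam < c * (1 - 1e-7))
    bias = float(np.mean(y[free] - decision(X[free]))) if free.any() else 0.0
    slack = np.maximum(0.0, 1.0 - y * (decision(X) + bias))
    objective = 0.5 * (lam * y) @ K @ (lam * y) + float(c @ slack)
    return {
        "lam": lam,
        "bias": bias,
        "objective": objective,
        "decision": lambda Z: decision(Z) + bias,
    }


def random_weighted_instance(seed):
    """Small random P / RN / ambiguous instance with weights and penalties."""
    rng = np.random.default_rng(seed)
    n_p, n_rn = rng.integers(3, 8), rng.integers(3, 8)
    n_a, d = rng.integers(0, 10), rng.integers(2, 6)
    X_p = rng.normal(1, 1, (n_p, d))
    X_rn = rng.normal(-1, 1, (n_rn, d))
    X_a = rng.normal(0, 1, (n_a, d)) if n_a else None
    wp = rng.random(n_a)
    W = np.c_[wp, 1 - wp] if n_a else None
    cs = rng.uniform(0.3, 3.0, 4)
    return X_p, X_rn, X_a, W, cs, 1.0 / d
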