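"""Independent reference solvers used to check the path solver.

These deliberately avoid the package's own optimization code paths: the
constrained weighted-lasso problem is re-solved through a general-purpose
NLP solver (SLSQP on the smooth lifted split alpha = alpha+ - alpha-), a
dense grid search, or closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def slsqp_solve(
    Z: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, float]:
    """Solve the zero-sum weighted lasso via SLSQP on the lifted problem.

    Returns (alpha, objective value) where the objective is
    (1/2n)||y~ - Z~ a||^2 + lam * w'|a| on centered data.
    """
    n, m = Z.shape
    yc = y - y.mean() if fit_intercept else y.astype(float)
    Zc = Z - Z.mean(axis=0) if fit_intercept else Z.astype(float)

    def obj(v: np.ndarray) -> float:
        a = v[:m] - v[m:]
        r = yc - Zc @ a
        return 0.5 * float(r @ r) / n + lam * float(w @ (v[:m] + v[m:]))

    def jac(v: np.ndarray) -> np.ndarray:
        g = -Zc.T @ (yc - Zc @ (v[:m] - v[m:])) / n
        return np.concatenate([g + lam * w, -g + lam * w])

    cons = [{
        "type": "eq",
        "fun": lambda v: float(np.sum(v[:m]) - np.sum(v[m:])),
        "jac": lambda v: np.concatenate([np.ones(m), -np.ones(m)]),
    }]
    res = minimize(
        obj, np.zeros(2 * m), jac=jac, method="SLSQP",
        bounds=[(0.0, None)] * (2 * m), constraints=cons,
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    alpha = res.x[:m] - res.x[m:]
    return alpha, float(res.fun)


def lambda_max_grid(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, fit_intercept: bool = True,
    n_points: int = 1_000_000,
) -> float:
    """Dense grid search for min_mu max_u |c_u - mu| / w_u."""
    n = len(y)
    yc = y - y.mean() if fit_intercept else y.astype(float)
    Zc = Z - Z.mean(axis=0) if fit_intercept else Z.astype(float)
    c = Zc.T @ yc / n
    mus = np.linspace(c.min(), c.max(), n_points)
    vals = np.abs(c[:, None] - mus[None, :]) / np.asarray(w)[:, None]
    return float(vals.max(axis=0).min())


def two_column_path(
    Z: np.ndarray, y: np.ndarray, lambdas: np.ndarray, fit_intercept: bool = True,
) -> np.ndarray:
    """Closed form for m=2, unit weights: alpha = (t, -t) with t a 1-D lasso.

    The constraint reduces the problem to the single feature d = Z1 - Z2
    with penalty 2*lam*|t|; t is the soft-thresholded least squares.
    """
    n = len(y)
    yc = y - y.mean() if fit_intercept else y.astype(float)
    Zc = Z - Z.mean(axis=0) if fit_intercept else Z.astype(float)
    d = Zc[:, 0] - Zc[:, 1]
    dd = float(d @ d) / n
    dy = float(d @ yc) / n
    out = np.zeros((2, len(lambdas)))
    for k, lam in enumerate(lambdas):
        t = np.sign(dy) * max(abs(dy) - 2 * lam, 0.0) / dd if dd > 0 else 0.0
        out[:, k] = (t, -t)
    return out


def brute_force_loo(fit_one, X_rows: int) -> np.ndarray:
    """Utility: leave-one-out residual loop; fit_one(train_idx, test_idx)."""
    errs = []
    for i in range(X_rows):
        train = [j for j in range(X_rows) if j != i]
        errs.append(fit_one(train, [i]))
    return np.asarray(errs)
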