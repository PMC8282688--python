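"""Zero-sum-constrained weighted-lasso path solver.

Solves, for a decreasing grid of penalty levels lambda,

    minimize_alpha  (1/2n) ||y~ - Z~ alpha||^2 + lambda * sum_u w_u |alpha_u|
    subject to      1' alpha = 0,

where ``y~``/``Z~`` are the response and features centered when an intercept
is requested.  The constraint makes the fit a log-contrast model: predictions
depend only on ratios of the underlying geometric means, never on per-sample
scale.

Algorithm: an active-set method with exact restricted solves, warm-started
along a geometric lambda grid.  For a hypothesized support and sign pattern
the equality-constrained quadratic subproblem is solved exactly through its
bordered KKT system; coordinates whose solved sign disagrees are dropped,
and the worst violator of the stationarity conditions (evaluated at the
optimal constraint multiplier) is added, until the KKT certificate falls
below tolerance.  Every grid point is therefore *certified*, never merely
"converged".  If the active set cycles (degenerate designs), a few hundred
ADMM iterations re-estimate the support and the active set is restarted.

Exactly duplicated feature columns (non-branching taxonomy chains) make the
l1 solution non-unique; the solver works on deduplicated columns, assigning
each duplicate group the smallest weight in the group (ties broken toward
the last, i.e. deepest, column) and reporting the coefficient on that
representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import minimize_scalar

from .features import duplicate_column_groups

__all__ = [
    "TracProblem",
    "PathSolution",
    "lambda_max",
    "solve_path",
    "kkt_certificate",
]

FEAS_TOL = 1e-8  # |1' alpha| feasibility tolerance


@dataclass
class TracProblem:
    """In-memory optimization problem: response, features, penalty weights."""

    y: np.ndarray
    Z: np.ndarray
    w: np.ndarray
    fit_intercept: bool = True
    column_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Z = np.asarray(self.Z, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        n, m = self.Z.shape
        if self.y.shape[0] != n:
            raise ValueError("y length does not match number of rows of Z")
        if self.w.shape[0] != m:
            raise ValueError("weight length does not match number of columns of Z")
        if np.any(self.w <= 0):
            raise ValueError("all penalty weights must be > 0")
        if not (np.all(np.isfinite(self.Z)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in Z or y")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if np.ptp(self.y) == 0:
            warnings.warn("response is constant across samples", stacklevel=2)

    # centered views -------------------------------------------------------
    @property
    def y_centered(self) -> np.ndarray:
        return self.y - self.y.mean() if self.fit_intercept else self.y

    @property
    def Z_centered(self) -> np.ndarray:
        return self.Z - self.Z.mean(axis=0) if self.fit_intercept else self.Z

    def objective(self, alpha: np.ndarray, lam: float) -> float:
        r = self.y_centered - self.Z_centered @ alpha
        return 0.5 * float(r @ r) / len(self.y) + lam * float(self.w @ np.abs(alpha))

    def intercept(self, alpha: np.ndarray) -> float:
        if not self.fit_intercept:
            return 0.0
        return float(self.y.mean() - self.Z.mean(axis=0) @ alpha)


@dataclass
class PathSolution:
    """Solutions along a decreasing lambda grid."""

    lambdas: np.ndarray
    alpha: np.ndarray  # (m, n_lambda)
    intercept: np.ndarray
    kkt_residual: np.ndarray
    n_nonzero: np.ndarray
    column_ids: list[str] | None = None
    n_iter: np.ndarray | None = None

    def alpha_at(self, lam: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.alpha[:, k]


def lambda_max(problem: TracProblem) -> float:
    """Smallest lambda at which alpha = 0 is optimal.

    The zero vector satisfies the stationarity conditions iff there is a
    multiplier mu with |c_u - mu| <= lambda * w_u for all u, where
    c = Z~' y~ / n; hence lambda_max = min_mu max_u |c_u - mu| / w_u.  This
    1-D weighted Chebyshev-center problem has the closed form
    max_{u,v} (c_u - c_v) / (w_u + w_v).
    """
    c = problem.Z_centered.T @ problem.y_centered / len(problem.y)
    w = problem.w
    diff = c[:, None] - c[None, :]
    wsum = w[:, None] + w[None, :]
    return max(float(np.max(diff / wsum)), 0.0)


def _cert_value(
    c: np.ndarray, active: np.ndarray, sign: np.ndarray, lam: float, w: np.ndarray
) -> tuple[float, float]:
    """Minimal stationarity violation over the constraint multiplier mu.

    ``c`` is the negative gradient Z~'(y~ - Z~ alpha)/n.  The violation
    max_u dist(c_u - mu, lam * w_u * d|alpha_u|) is convex piecewise linear
    in mu; it is minimized by a bounded scalar search refined against every
    kink location.  Returns (violation, argmin mu).
    """

    def f(mu: float) -> float:
        v = 0.0
        if active.any():
            v = float(np.max(np.abs(c[active] - mu - lam * w[active] * sign[active])))
        if (~active).any():
            slack = np.abs(c[~active] - mu) - lam * w[~active]
            v = max(v, float(np.max(slack)))
        return max(v, 0.0)

    cand = []
    if active.any():
        cand.append(c[active] - lam * w[active] * sign[active])
    if (~active).any():
        cand.append(c[~active] - lam * w[~active])
        cand.append(c[~active] + lam * w[~active])
    cand = np.concatenate(cand) if cand else np.array([0.0])
    lo, hi = float(cand.min()) - 1.0, float(cand.max()) + 1.0
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-13})
    best_mu = float(res.x)
    best = float(res.fun)
    for mu in cand:
        v = f(float(mu))
        if v < best:
            best, best_mu = v, float(mu)
    return best, best_mu


def kkt_certificate(problem: TracProblem, alpha: np.ndarray, lam: float) -> float:
    """Max stationarity violation of ``alpha`` for the problem at ``lam``.

    Zero (up to round-off) certifies optimality.  ``alpha`` must satisfy the
    zero-sum constraint to within 1e-8.
    """
    alpha = np.asarray(alpha, dtype=float).ravel()
    if abs(alpha.sum()) > FEAS_TOL * max(1.0, np.abs(alpha).max(initial=0.0)):
        raise ValueError(f"alpha violates the zero-sum constraint: sum={alpha.sum()}")
    r = problem.y_centered - problem.Z_centered @ alpha
    c = problem.Z_centered.T @ r / len(problem.y)
    value, _ = _cert_value(c, alpha != 0, np.sign(alpha), lam, problem.w)
    return value


def _soft(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _restricted_solve(
    Q: np.ndarray, c0: np.ndarray, S: np.ndarray, sign: np.ndarray, lam: float,
    w: np.ndarray,
) -> np.ndarray:
    """Exact solve of the sign-fixed quadratic on support ``S``.

    Solves  Q_SS a_S - c0_S + lam w_S s_S + nu 1 = 0,  1' a_S = 0.
    """
    idx = np.flatnonzero(S)
    k = idx.size
    M = np.empty((k + 1, k + 1))
    M[:k, :k] = Q[np.ix_(idx, idx)]
    M[:k, k] = 1.0
    M[k, :k] = 1.0
    M[k, k] = 0.0
    rhs = np.empty(k + 1)
    rhs[:k] = c0[idx] - lam * w[idx] * sign[idx]
    rhs[k] = 0.0
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    if not np.all(np.isfinite(sol)):
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    a_S = sol[:k]
    return a_S - a_S.sum() / k  # exact constraint feasibility


def _active_set(
    Q: np.ndarray, c0: np.ndarray, w: np.ndarray, lam: float, tol: float,
    alpha0: np.ndarray, max_pass: int,
) -> tuple[np.ndarray, float, int]:
    """Certified active-set solve warm-started at ``alpha0``.

    Returns (alpha, kkt_residual, passes); the residual may exceed ``tol``
    if the pass budget is exhausted (caller falls back to ADMM).
    """
    m = len(c0)
    alpha = alpha0.copy()
    S = alpha != 0
    sign = np.sign(alpha)
    best = (np.zeros(m), np.inf)
    seen: set[bytes] = set()
    for it in range(1, max_pass + 1):
        state = np.concatenate([S.astype(np.int8), sign.astype(np.int8)]).tobytes()
        if state in seen:
            return best[0], best[1], it  # cycle: let the fallback take over
        seen.add(state)
        if S.any():
            a_S = _restricted_solve(Q, c0, S, sign, lam, w)
            idx = np.flatnonzero(S)
            wrong = a_S * sign[idx] < 0
            if wrong.any():
                # step toward a_S until the first coefficient crosses zero,
                # drop that coordinate (Lawson-Hanson style partial step)
                cur = alpha[idx]
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = np.where(wrong, cur / (cur - a_S), np.inf)
                t = np.where(np.isfinite(t) & (t >= 0), t, np.inf)
                j_local = int(np.argmin(t))
                step = min(float(t[j_local]), 1.0)
                alpha[idx] = cur + step * (a_S - cur)
                alpha[idx[j_local]] = 0.0
                S[idx[j_local]] = False
                sign[idx[j_local]] = 0.0
                continue
            alpha = np.zeros(m)
            alpha[idx] = a_S
        else:
            alpha = np.zeros(m)
        c = c0 - Q[:, S] @ alpha[S] if S.any() else c0.copy()
        value, mu = _cert_value(c, alpha != 0, np.sign(alpha), lam, w)
        if value < best[1]:
            best = (alpha.copy(), value)
        if value <= tol:
            return alpha, value, it
        # add the worst stationarity violator outside the current support
        slack = np.abs(c - mu) - lam * w
        slack[S] = -np.inf
        j = int(np.argmax(slack))
        if not np.isfinite(slack[j]) or slack[j] <= tol:
            # violation sits inside the support (degenerate restricted
            # solve): give up and let the fallback handle it
            return best[0], best[1], it
        S[j] = True
        sign[j] = np.sign(c[j] - mu)
    return best[0], best[1], max_pass


def solve_path(
    problem: TracProblem,
    n_lambda: int = 50,
    min_fraction: float = 1e-3,
    lambdas: np.ndarray | None = None,
    rtol: float = 1e-7,
    max_iter: int = 100_000,
) -> PathSolution:
    """Solve the constrained weighted lasso along a lambda grid.

    The grid is geometric from ``lambda_max`` down to
    ``min_fraction * lambda_max`` unless ``lambdas`` is given explicitly.
    Each grid point is warm-started from the previous one and certified to a
    KKT residual of ``rtol * max(1, ||Z~'y~ / n||_inf)``.
    """
    n, m_full = problem.Z.shape
    Zc_full = problem.Z_centered
    yc = problem.y_centered

    # collapse duplicated columns; representative = min weight, then deepest
    groups = duplicate_column_groups(Zc_full)
    rep_weight: dict[int, float] = {}
    for g in groups:
        wmin = problem.w[g].min()
        best = max(j for j in g if problem.w[j] == wmin)
        rep_weight[best] = wmin
    reps = sorted(rep_weight)
    Zc = Zc_full[:, reps]
    w = np.array([rep_weight[j] for j in reps])

    m = len(reps)
    Q = Zc.T @ Zc / n
    c0 = Zc.T @ yc / n
    tol = rtol * max(1.0, float(np.abs(c0).max(initial=0.0)))

    lam_max = _lambda_max_from(c0, w)
    if lambdas is None:
        if lam_max <= 1e-14:
            grid = np.array([0.0])
        else:
            grid = lam_max * np.geomspace(1.0, min_fraction, n_lambda)
    else:
        grid = np.asarray(lambdas, dtype=float)

    alpha_red = np.zeros((m, len(grid)))
    resid = np.zeros(len(grid))
    iters = np.zeros(len(grid), dtype=int)

    lu = None  # ADMM factorization, built lazily on first fallback
    rho = max(float(np.trace(Q)) / max(m, 1), 1e-6)

    warm = np.zeros(m)
    max_pass = 4 * m + 50
    for k, lam in enumerate(grid):
        if lam <= 0:
            alpha = _constrained_ls(Q, c0)
            value, _ = _cert_value(c0 - Q @ alpha, alpha != 0, np.sign(alpha),
                                   0.0, w)
            alpha_red[:, k], resid[k] = alpha, value
            warm = alpha
            continue
        alpha, value, it = _active_set(Q, c0, w, lam, tol, warm, max_pass)
        total_it = it
        if value > tol and m > 1:
            # ADMM restarts to escape active-set cycling
            if lu is None:
                M = np.zeros((m + 1, m + 1))
                M[:m, :m] = Q + rho * np.eye(m)
                M[:m, m] = 1.0
                M[m, :m] = 1.0
                lu = lu_factor(M)
            z = alpha.copy()
            u = np.zeros(m)
            rhs = np.empty(m + 1)
            rhs[m] = 0.0
            admm_done = 0
            while value > tol and admm_done < max_iter:
                for _ in range(250):
                    rhs[:m] = c0 + rho * (z - u)
                    x = lu_solve(lu, rhs)[:m]
                    z = _soft(x + u, lam * w / rho)
                    u += x - z
                admm_done += 250
                alpha2, value2, it2 = _active_set(Q, c0, w, lam, tol, z,
                                                  max_pass)
                total_it += 250 + it2
                if value2 < value:
                    alpha, value = alpha2, value2
        if value > tol:
            warnings.warn(
                f"path solver did not certify lambda={lam:.3g} "
                f"(KKT residual {value:.2e} > {tol:.2e})",
                stacklevel=2,
            )
        alpha_red[:, k], resid[k] = alpha, value
        iters[k] = total_it
        warm = alpha

    # expand to the full column set
    alpha_full = np.zeros((m_full, len(grid)))
    alpha_full[reps, :] = alpha_red
    intercepts = np.array(
        [problem.intercept(alpha_full[:, k]) for k in range(len(grid))]
    )
    support_tol = 1e-8
    nnz = (np.abs(alpha_full) > support_tol *
           np.maximum(1.0, np.abs(alpha_full).max(axis=0))).sum(axis=0)
    return PathSolution(
        lambdas=grid,
        alpha=alpha_full,
        intercept=intercepts,
        kkt_residual=resid,
        n_nonzero=nnz,
        column_ids=problem.column_ids,
        n_iter=iters,
    )


def _lambda_max_from(c0: np.ndarray, w: np.ndarray) -> float:
    diff = c0[:, None] - c0[None, :]
    wsum = w[:, None] + w[None, :]
    return max(float(np.max(diff / wsum)), 0.0)


def _constrained_ls(Q: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Unpenalized equality-constrained least squares (lambda = 0)."""
    m = len(c0)
    M = np.zeros((m + 1, m + 1))
    M[:m, :m] = Q
    M[:m, m] = 1.0
    M[m, :m] = 1.0
    rhs = np.zeros(m + 1)
    rhs[:m] = c0
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    alpha = sol[:m]
    return alpha - alpha.sum() / m
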