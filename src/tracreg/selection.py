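"""Cross-validated lambda selection with the one-standard-error rule.

The lambda grid is computed once on the full training data and reused in
every fold (glmnet-style), so fold curves are comparable pointwise.  For
each fold the model is refit on the complement and scored by mean squared
error on the held-out samples; the per-lambda mean and standard error
(standard deviation of fold means / sqrt(k)) define the curve from which
``lambda_min`` (minimum mean error) and ``lambda_1se`` (largest lambda whose
mean error is within one standard error of the minimum) are read off.  The
1SE rule is the default selector: it deliberately prefers sparser, more
interpretable aggregation models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import CountTable
from .model import TracFit, fit_sparse_log_contrast, fit_trac, selected_support
from .taxonomy import TaxTree


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_error: np.ndarray
    se_error: np.ndarray
    lambda_min: float
    lambda_1se: float
    fold_assignment: np.ndarray
    seed: int

    @property
    def index_min(self) -> int:
        return int(np.argmin(self.mean_error))

    @property
    def index_1se(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.lambda_1se)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "mean_error": self.mean_error,
             "se_error": self.se_error}
        )


def fold_partition(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition of ``range(n)`` into k near-equal folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def one_se_rule(cv: CVResult) -> float:
    """Largest lambda with mean error within one SE of the minimum."""
    i_min = int(np.argmin(cv.mean_error))
    threshold = cv.mean_error[i_min] + cv.se_error[i_min]
    ok = np.flatnonzero(cv.mean_error <= threshold)
    return float(cv.lambdas[ok[np.argmax(cv.lambdas[ok])]])


def cross_validate(
    counts: CountTable,
    y: np.ndarray,
    tree: TaxTree | None,
    a: float = 1.0,
    k: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
    n_lambda: int = 50,
    min_fraction: float = 1e-3,
    fit_intercept: bool = True,
    model: str = "trac",
) -> tuple[CVResult, TracFit]:
    """k-fold CV over a common lambda path; returns the CV curve and the
    full-data fit (lambda not yet selected).

    ``model`` is ``"trac"`` (needs ``tree``) or ``"sparse_log_contrast"``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = counts.n_samples
    if len(y) != n:
        raise ValueError("response length does not match sample count")

    def _fit(sub_counts: CountTable, sub_y: np.ndarray, lambdas=None) -> TracFit:
        if model == "trac":
            if tree is None:
                raise ValueError("trac model requires a taxonomy tree")
            return fit_trac(sub_counts, sub_y, tree, a=a, pseudocount=pseudocount,
                            n_lambda=n_lambda, min_fraction=min_fraction,
                            fit_intercept=fit_intercept, lambdas=lambdas)
        if model == "sparse_log_contrast":
            return fit_sparse_log_contrast(
                sub_counts, sub_y, pseudocount=pseudocount, n_lambda=n_lambda,
                min_fraction=min_fraction, fit_intercept=fit_intercept,
                lambdas=lambdas)
        raise ValueError(f"unknown model kind {model!r}")

    full_fit = _fit(counts, y)
    grid = full_fit.path.lambdas

    assignment = fold_partition(n, k, seed)
    fold_mse = np.empty((k, len(grid)))
    for f in range(k):
        test = assignment == f
        train = ~test
        sub = CountTable(counts.X[train], list(np.array(counts.sample_ids)[train]),
                         list(counts.taxon_ids))
        fit_f = _fit(sub, y[train], lambdas=grid)
        held = CountTable(counts.X[test], list(np.array(counts.sample_ids)[test]),
                          list(counts.taxon_ids))
        for j in range(len(grid)):
            fit_f.select(index=j)
            pred = fit_f.predict(held)
            fold_mse[f, j] = float(np.mean((y[test] - pred) ** 2))

    mean_error = fold_mse.mean(axis=0)
    se_error = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(mean_error))
    cv = CVResult(
        lambdas=grid,
        mean_error=mean_error,
        se_error=se_error,
        lambda_min=float(grid[i_min]),
        lambda_1se=np.nan,
        fold_assignment=assignment,
        seed=int(seed),
    )
    cv.lambda_1se = one_se_rule(cv)
    return cv, full_fit


def select_by_rule(fit: TracFit, cv: CVResult, rule: str = "1se") -> TracFit:
    """Fix the fit's lambda by CV rule: ``"1se"`` (default) or ``"min"``."""
    if rule == "1se":
        return fit.select(lam=cv.lambda_1se)
    if rule == "min":
        return fit.select(lam=cv.lambda_min)
    raise ValueError(f"unknown selection rule {rule!r}")


def test_metrics(fit: TracFit, test_counts: CountTable, test_y: np.ndarray) -> dict:
    """Out-of-sample MSE, Pearson r, and model sparsity at the chosen lambda.

    Pearson r is reported as NaN (undefined) when predictions or responses
    have zero variance, never raised as an error.
    """
    test_y = np.asarray(test_y, dtype=float).ravel()
    pred = fit.predict(test_counts)
    mse = float(np.mean((test_y - pred) ** 2))
    def _degenerate(v: np.ndarray) -> bool:
        return np.std(v) <= 1e-12 * (1.0 + float(np.abs(v).max(initial=0.0)))

    if _degenerate(pred) or _degenerate(test_y):
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, test_y)[0, 1])
    n_selected = int(selected_support(fit.alpha_hat).sum())
    return {"mse": mse, "pearson_r": r, "n_selected": n_selected}
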