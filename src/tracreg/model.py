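"""The tree-aggregated log-contrast estimator (trac) and its baseline.

The estimator fits a penalized linear model on the log-geometric-mean
features of every non-root taxonomy node,

    min_alpha (1/2n)||y - Z alpha - b||^2 + lambda sum_u w_u |alpha_u|,
    s.t. 1' alpha = 0,   with   w_u = |L_u|^(-a),

so a single nonzero alpha_u stands for the whole subtree rooted at u.  The
weight exponent ``a`` steers the preferred aggregation level: a=1 (default)
favors coarse subtrees, a=1/2 ("weighted") sits closer to the leaves, and a
sufficiently negative ``a`` prices every internal node out of the model,
recovering the sparse log-contrast regression on leaves only.  ``a`` is a
user-set control parameter, never tuned by model selection.

Node coefficients map back to an equivalent leaf-level coefficient vector
through the ancestry matrix: ``beta = A diag(1/|L_u|) alpha``, which is
constant on each selected subtree and again sums to zero.

An unpenalized intercept is fitted by centering the response and the feature
columns; responses in physical units (e.g. pg/ml) need the location shift,
and the zero-sum structure is unaffected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CountTable, FeatureMatrix, geom_features
from .solver import PathSolution, TracProblem, solve_path
from .taxonomy import AncestryMatrix, Lineage, TaxTree, ancestry_matrix, parse_lineages

SUPPORT_RTOL = 1e-8  # |alpha_u| > SUPPORT_RTOL * max(1, ||alpha||_inf) counts as selected


@dataclass
class WeightScheme:
    """Penalty weights w_u = |L_u|^(-a) for every non-root node."""

    a: float
    w: dict[str, float]


def compute_weights(tree: TaxTree, a: float = 1.0) -> WeightScheme:
    return WeightScheme(
        a=float(a),
        w={u: float(len(tree.leaf_sets[u])) ** (-a) for u in tree.column_order},
    )


def selected_support(alpha: np.ndarray) -> np.ndarray:
    """Boolean mask of coefficients counted as selected."""
    alpha = np.asarray(alpha, dtype=float)
    thresh = SUPPORT_RTOL * max(1.0, float(np.abs(alpha).max(initial=0.0)))
    return np.abs(alpha) > thresh


def alpha_to_beta(
    alpha: np.ndarray, anc: AncestryMatrix, leaf_counts: np.ndarray
) -> np.ndarray:
    """Map node coefficients to leaf coefficients: beta = A diag(1/|L_u|) alpha."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    leaf_counts = np.asarray(leaf_counts, dtype=float).ravel()
    if alpha.shape[0] != anc.A.shape[1] or leaf_counts.shape[0] != anc.A.shape[1]:
        raise ValueError("alpha/leaf_counts length must match ancestry columns")
    return np.asarray(anc.A @ (alpha / leaf_counts))


@dataclass
class TracFit:
    """A fitted aggregation path, optionally with a chosen lambda."""

    tree: TaxTree
    weights: WeightScheme
    path: PathSolution
    pseudocount: float
    fit_intercept: bool = True
    chosen_lambda: float | None = None
    chosen_index: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def column_order(self) -> list[str]:
        return self.tree.column_order

    def select(self, lam: float | None = None, index: int | None = None) -> "TracFit":
        """Fix the working lambda (by value or by grid index)."""
        if index is None:
            if lam is None:
                raise ValueError("give either lam or index")
            index = int(np.argmin(np.abs(self.path.lambdas - lam)))
        self.chosen_index = int(index)
        self.chosen_lambda = float(self.path.lambdas[index])
        return self

    @property
    def alpha_hat(self) -> np.ndarray:
        if self.chosen_index is None:
            raise ValueError("no lambda chosen yet; call select()")
        return self.path.alpha[:, self.chosen_index]

    @property
    def intercept_hat(self) -> float:
        if self.chosen_index is None:
            raise ValueError("no lambda chosen yet; call select()")
        return float(self.path.intercept[self.chosen_index])

    @property
    def beta_hat(self) -> np.ndarray:
        anc = ancestry_matrix(self.tree)
        sizes = np.array([len(self.tree.leaf_sets[u]) for u in anc.column_order])
        return alpha_to_beta(self.alpha_hat, anc, sizes)

    @property
    def selected(self) -> pd.DataFrame:
        """Nonzero aggregations at the chosen lambda: (taxon, level, alpha)."""
        alpha = self.alpha_hat
        mask = selected_support(alpha)
        rows = [
            {
                "taxon": self.tree.display_name(u),
                "level": self.tree.node_rank.get(u, "?"),
                "alpha": float(alpha[k]),
                "path": u,
            }
            for k, u in enumerate(self.column_order)
            if mask[k]
        ]
        df = pd.DataFrame(rows, columns=["taxon", "level", "alpha", "path"])
        return df.reindex(df["alpha"].abs().sort_values(ascending=False).index
                          ).reset_index(drop=True)

    def predict(self, new_counts: CountTable) -> np.ndarray:
        return predict(self, new_counts)

    # ---- serialization ---------------------------------------------------
    def to_json(self) -> str:
        if self.chosen_index is None:
            raise ValueError("select a lambda before serializing")
        payload = {
            "tree_hash": tree_hash(self.tree),
            "leaf_ids": self.tree.leaf_ids,
            "ranks": list(self.tree.ranks),
            "lineages": [
                {"taxon_id": ln.taxon_id, "ranked_names": [list(t) for t in ln.ranked_names]}
                for ln in self.tree.lineages
            ],
            "pseudocount": self.pseudocount,
            "a": self.weights.a,
            "fit_intercept": self.fit_intercept,
            "lambdas": self.path.lambdas.tolist(),
            "chosen_lambda": self.chosen_lambda,
            "chosen_index": self.chosen_index,
            "alpha_hat": dict(zip(self.column_order, self.alpha_hat.tolist())),
            "intercept": self.intercept_hat,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=1)

    @staticmethod
    def from_json(text: str) -> "TracFit":
        d = json.loads(text)
        rows = [
            Lineage(e["taxon_id"], tuple(tuple(t) for t in e["ranked_names"]))
            for e in d["lineages"]
        ]
        tree = parse_lineages(rows)
        if tree_hash(tree) != d["tree_hash"]:
            raise ValueError("taxonomy hash mismatch on load")
        weights = compute_weights(tree, d["a"])
        m = len(tree.column_order)
        lambdas = np.asarray(d["lambdas"], dtype=float)
        alpha = np.zeros((m, len(lambdas)))
        k = int(d["chosen_index"])
        avec = np.array([d["alpha_hat"][u] for u in tree.column_order])
        alpha[:, k] = avec
        path = PathSolution(
            lambdas=lambdas,
            alpha=alpha,
            intercept=np.full(len(lambdas), d["intercept"], dtype=float),
            kkt_residual=np.full(len(lambdas), np.nan),
            n_nonzero=np.full(len(lambdas), -1),
            column_ids=tree.column_order,
        )
        fit = TracFit(
            tree=tree,
            weights=weights,
            path=path,
            pseudocount=float(d["pseudocount"]),
            fit_intercept=bool(d["fit_intercept"]),
            provenance=d.get("provenance", {}),
        )
        return fit.select(index=k)


def tree_hash(tree: TaxTree) -> str:
    h = hashlib.sha256()
    for u in tree.nodes:
        h.update(u.encode())
        h.update(b"\x00")
    for t in tree.leaf_ids:
        h.update(t.encode())
        h.update(b"\x01")
    return h.hexdigest()


def fit_trac(
    counts: CountTable,
    y: np.ndarray,
    tree: TaxTree,
    a: float = 1.0,
    pseudocount: float = 1.0,
    n_lambda: int = 50,
    min_fraction: float = 1e-3,
    fit_intercept: bool = True,
    lambdas: np.ndarray | None = None,
) -> TracFit:
    """Fit the full aggregation path (lambda selection deferred).

    Composes feature construction, the |L_u|^(-a) weight scheme, and the
    constrained path solver.  Returns a :class:`TracFit` whose ``path`` holds
    coefficients on the whole grid; call ``select`` (typically with a
    cross-validated lambda) before predicting.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != counts.n_samples:
        raise ValueError("response length does not match number of samples")
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    feats = geom_features(counts, tree, pseudocount)
    scheme = compute_weights(tree, a)
    w = np.array([scheme.w[u] for u in feats.column_order])
    problem = TracProblem(
        y=y, Z=feats.Z, w=w, fit_intercept=fit_intercept,
        column_ids=feats.column_order,
    )
    path = solve_path(problem, n_lambda=n_lambda, min_fraction=min_fraction,
                      lambdas=lambdas)
    return TracFit(
        tree=tree,
        weights=scheme,
        path=path,
        pseudocount=float(pseudocount),
        fit_intercept=fit_intercept,
        provenance={
            "a": float(a),
            "pseudocount": float(pseudocount),
            "n_lambda": int(len(path.lambdas)),
            "min_fraction": float(min_fraction),
        },
    )


def star_tree(taxon_ids: list[str], rank: str = "base") -> TaxTree:
    """Depth-1 taxonomy: every taxon a direct child of the root."""
    rows = [Lineage(t, ((rank, t),)) for t in taxon_ids]
    return parse_lineages(rows)


def fit_sparse_log_contrast(
    counts: CountTable,
    y: np.ndarray,
    pseudocount: float = 1.0,
    n_lambda: int = 50,
    min_fraction: float = 1e-3,
    fit_intercept: bool = True,
    lambdas: np.ndarray | None = None,
) -> TracFit:
    """Sparse log-contrast regression: the leaf-only baseline.

    Identical machinery on a star taxonomy, so the features are plain log
    counts with unit weights — the classical l1-penalized log-contrast model.
    """
    tree = star_tree(list(counts.taxon_ids))
    star_counts = CountTable(counts.X, list(counts.sample_ids), list(counts.taxon_ids))
    return fit_trac(
        star_counts, y, tree, a=1.0, pseudocount=pseudocount, n_lambda=n_lambda,
        min_fraction=min_fraction, fit_intercept=fit_intercept, lambdas=lambdas,
    )


def predict(fit: TracFit, new_counts: CountTable) -> np.ndarray:
    """Predict responses for new samples at the chosen lambda.

    New taxa must match the training leaves (any order); the training
    pseudocount is reused.  Because the coefficients sum to zero, predictions
    are invariant to per-sample rescaling of positive counts when the
    pseudocount is zero.
    """
    if fit.chosen_index is None:
        raise ValueError("no lambda chosen yet; call select()")
    want = list(fit.tree.leaf_ids)
    have = set(new_counts.taxon_ids)
    missing = [t for t in want if t not in have]
    extra = [t for t in new_counts.taxon_ids if t not in set(want)]
    if missing or extra:
        raise ValueError(
            f"taxa mismatch: missing from new data {missing[:10]}, "
            f"unknown to model {extra[:10]}"
        )
    aligned = new_counts.reorder_taxa(want)
    feats = geom_features(aligned, fit.tree, fit.pseudocount)
    return fit.intercept_hat + feats.Z @ fit.alpha_hat


def training_loss_beta(
    counts: CountTable, y: np.ndarray, fit: TracFit
) -> tuple[float, float]:
    """Training MSE evaluated in alpha-form and in leaf (beta) form.

    The aggregation identity log(geom(X;T)) alpha = log(X+pc) beta makes the
    two equal to machine precision; both are returned for verification.
    """
    y = np.asarray(y, dtype=float).ravel()
    feats = geom_features(counts, fit.tree, fit.pseudocount)
    pred_alpha = fit.intercept_hat + feats.Z @ fit.alpha_hat
    logX = np.log(counts.X + fit.pseudocount)
    pred_beta = fit.intercept_hat + logX @ fit.beta_hat
    return (
        float(np.mean((y - pred_alpha) ** 2)),
        float(np.mean((y - pred_beta) ** 2)),
    )
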