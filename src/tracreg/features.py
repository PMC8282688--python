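"""Count tables and log-geometric-mean feature construction.

Each non-root node ``u`` of the taxonomy contributes one feature column:
the log of the geometric mean of the base-level counts in its subtree,

    Z[i, u] = (1/|L_u|) * sum_{j in L_u} log(X[i, j] + pseudocount),

so ``Z = log(X + pc) @ A @ diag(1/|L_u|)`` with ``A`` the ancestry matrix.
Leaf columns reduce to plain log counts.  Because predictions are built from
zero-sum combinations of these columns, any per-sample rescaling of the
counts only shifts each row of ``Z`` by a constant and cancels out.

``aggregate_to_rank`` implements the conventional alternative: arithmetic
(summed) aggregation of counts to a fixed rank, producing a new base level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .taxonomy import TaxTree, ancestry_matrix


@dataclass
class CountTable:
    """Sample-by-taxon nonnegative count matrix with identifiers."""

    X: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x taxa)")
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValueError(
                f"shape {self.X.shape} inconsistent with {len(self.sample_ids)} "
                f"sample ids and {len(self.taxon_ids)} taxon ids"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.X < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.X.shape[1]

    def reorder_taxa(self, taxon_ids: list[str]) -> "CountTable":
        idx = {t: j for j, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in idx]
        if missing:
            raise ValueError(f"taxa absent from count table: {missing}")
        order = [idx[t] for t in taxon_ids]
        return CountTable(self.X[:, order], list(self.sample_ids), list(taxon_ids))


@dataclass
class FeatureMatrix:
    """Log-geometric-mean features, one column per non-root node."""

    Z: np.ndarray
    column_order: list[str]
    pseudocount: float


def geom_features(
    counts: CountTable, tree: TaxTree, pseudocount: float = 1.0
) -> FeatureMatrix:
    """Compute ``log(geom(X; T))`` for every non-root node of the tree.

    ``counts.taxon_ids`` must match the tree's leaf ids in order.  A positive
    pseudocount is required whenever zero counts are present.
    """
    if list(counts.taxon_ids) != list(tree.leaf_ids):
        raise ValueError("count table taxa do not match tree leaves (order-sensitive)")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(counts.X <= 0):
        raise ValueError("zero counts present: log undefined without a pseudocount")
    anc = ancestry_matrix(tree)
    logX = np.log(counts.X + pseudocount)
    sizes = np.asarray(anc.A.sum(axis=0)).ravel()
    Z = (logX @ anc.A) / sizes
    return FeatureMatrix(Z=np.asarray(Z), column_order=anc.column_order,
                         pseudocount=float(pseudocount))


def aggregate_to_rank(counts: CountTable, tree: TaxTree, rank: str) -> CountTable:
    """Sum counts over the subtrees rooted at ``rank``-level nodes.

    The result is usable as a new (coarser) base level; its taxon ids are the
    full node paths, matching :func:`tracreg.taxonomy.truncated_lineages`.
    """
    if list(counts.taxon_ids) != list(tree.leaf_ids):
        raise ValueError("count table taxa do not match tree leaves (order-sensitive)")
    nodes = tree.rank_nodes(rank)
    X_new = np.column_stack(
        [counts.X[:, tree.leaf_sets[u]].sum(axis=1) for u in nodes]
    )
    return CountTable(X_new, list(counts.sample_ids), list(nodes))


def column_dedup_report(
    Z: np.ndarray, column_ids: list[str] | None = None, tol: float = 1e-12
) -> list[list[str]]:
    """Groups of feature columns equal within ``tol`` (groups of size >= 2).

    Chain nodes with a single child produce exactly duplicated columns; the
    solver resolves which group member carries the coefficient, this report
    makes the degeneracy visible to the user.
    """
    Z = np.asarray(Z, dtype=float)
    m = Z.shape[1]
    if column_ids is None:
        column_ids = [str(k) for k in range(m)]
    groups = duplicate_column_groups(Z, tol)
    return [[column_ids[k] for k in g] for g in groups if len(g) > 1]


def duplicate_column_groups(Z: np.ndarray, tol: float = 1e-12) -> list[list[int]]:
    """Partition column indices into groups of (near-)identical columns.

    Columns are sorted lexicographically, then adjacent columns are chained
    into a group while their max absolute difference is <= ``tol``.  Returns
    every group (singletons included), each sorted ascending.
    """
    m = Z.shape[1]
    if m == 0:
        return []
    order = np.lexsort(Z[::-1])  # lexicographic by rows
    groups: list[list[int]] = [[int(order[0])]]
    for prev, cur in zip(order[:-1], order[1:]):
        if np.max(np.abs(Z[:, cur] - Z[:, prev])) <= tol:
            groups[-1].append(int(cur))
        else:
            groups.append([int(cur)])
    return [sorted(g) for g in groups]
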