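"""Repeated train/test evaluation of aggregation models.

Mirrors the standard protocol for comparing compositional regression
models: repeatedly split samples into a 2/3 training and 1/3 test part;
on each training part run 5-fold CV with the 1SE rule; record out-of-sample
MSE, Pearson correlation, and model sparsity; average over repeats.  Models
can be evaluated at different base levels (e.g. OTU, genus, family) by
arithmetically aggregating the counts to a rank before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CountTable, aggregate_to_rank
from .model import TracFit
from .selection import cross_validate, select_by_rule, test_metrics
from .taxonomy import TaxTree, parse_lineages, truncated_lineages


@dataclass
class SplitPlan:
    """Reproducible repeated train/test partitions."""

    n: int
    n_repeats: int
    train_fraction: float
    seed: int
    assignments: list[np.ndarray] = field(default_factory=list)  # bool, True=train

    def train_idx(self, r: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[r])

    def test_idx(self, r: int) -> np.ndarray:
        return np.flatnonzero(~self.assignments[r])


def make_splits(
    n: int, n_repeats: int = 10, train_fraction: float = 2 / 3, seed: int = 0
) -> SplitPlan:
    """Draw ``n_repeats`` random train/test partitions.

    Train size is ``round(train_fraction * n)`` (nearest integer).  The same
    seed always reproduces the same plan.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(
            f"degenerate split: {n_train} train / {n - n_train} test from n={n}"
        )
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_train]] = True
        assignments.append(mask)
    return SplitPlan(n=n, n_repeats=n_repeats, train_fraction=train_fraction,
                     seed=int(seed), assignments=assignments)


@dataclass
class BenchmarkTable:
    """Per-repeat results plus the summary layouts."""

    results: pd.DataFrame          # one row per (repeat, method)
    summary: pd.DataFrame          # rows base_level, cols method: "error (sparsity)"
    rank_summary: pd.DataFrame     # mean per-rank selection counts per method
    n_excluded: int


def _method_label(method: dict) -> str:
    kind = method.get("kind", "trac")
    if kind == "sparse_log_contrast":
        lab = "log-contrast"
    else:
        lab = f"trac(a={method.get('a', 1.0):g})"
    return lab


def rank_selection_summary(
    fits: list[TracFit], ranks: tuple[str, ...] | None = None
) -> pd.Series:
    """Mean number of selected nodes per taxonomic rank across fits."""
    if ranks is None:
        ranks = fits[0].tree.ranks if fits else ()
    counts = pd.DataFrame(0.0, index=range(len(fits)), columns=list(ranks))
    for i, fit in enumerate(fits):
        for _, row in fit.selected.iterrows():
            if row["level"] in counts.columns:
                counts.loc[i, row["level"]] += 1
    if len(fits) == 0:
        return pd.Series(0.0, index=list(ranks))
    return counts.mean(axis=0)


def run_benchmark(
    counts: CountTable,
    y: np.ndarray,
    tree: TaxTree,
    methods: list[dict],
    plan: SplitPlan,
    cv_folds: int = 5,
    rule: str = "1se",
    pseudocount: float = 1.0,
    n_lambda: int = 50,
    min_fraction: float = 1e-3,
) -> BenchmarkTable:
    """Evaluate each method over every split of the plan.

    ``methods`` entries are dicts with keys ``kind`` ("trac" or
    "sparse_log_contrast"), ``a`` (trac only), and optional ``base_level``
    (a rank name; counts are summed to that rank before fitting).  Failed
    repeats (e.g. zero-variance training response) are recorded with NaN
    metrics and excluded from the means.
    """
    if not methods:
        raise ValueError("methods list is empty")
    y = np.asarray(y, dtype=float).ravel()
    base_rank = tree.ranks[-1]

    # pre-aggregate once per distinct base level
    levels = {m.get("base_level") or base_rank for m in methods}
    data_by_level: dict[str, tuple[CountTable, TaxTree]] = {}
    for lvl in levels:
        if lvl == base_rank:
            data_by_level[lvl] = (counts, tree)
        else:
            agg = aggregate_to_rank(counts, tree, lvl)
            sub_tree = parse_lineages(truncated_lineages(tree, lvl))
            agg = agg.reorder_taxa(list(sub_tree.leaf_ids))
            data_by_level[lvl] = (agg, sub_tree)

    rows = []
    fits_by_method: dict[str, list[TracFit]] = {}
    n_excluded = 0
    for r in range(plan.n_repeats):
        tr, te = plan.train_idx(r), plan.test_idx(r)
        for method in methods:
            lvl = method.get("base_level") or base_rank
            data, lvl_tree = data_by_level[lvl]
            label = _method_label(method)
            key = (lvl, label)
            record = {"repeat": r, "base_level": lvl, "method": label,
                      "mse": np.nan, "pearson_r": np.nan, "n_selected": np.nan,
                      "error": None}
            try:
                train = CountTable(data.X[tr],
                                   list(np.array(data.sample_ids)[tr]),
                                   list(data.taxon_ids))
                test = CountTable(data.X[te],
                                  list(np.array(data.sample_ids)[te]),
                                  list(data.taxon_ids))
                if np.ptp(y[tr]) == 0:
                    raise ValueError("zero-variance training response")
                cv, fit = cross_validate(
                    train, y[tr], lvl_tree,
                    a=method.get("a", 1.0), k=cv_folds,
                    seed=plan.seed * 1_000 + r,
                    pseudocount=pseudocount, n_lambda=n_lambda,
                    min_fraction=min_fraction,
                    model=method.get("kind", "trac"),
                )
                select_by_rule(fit, cv, rule)
                record.update(test_metrics(fit, test, y[te]))
                fits_by_method.setdefault(label, []).append(fit)
            except Exception as exc:  # recorded, never silently dropped
                record["error"] = str(exc)
                n_excluded += 1
            rows.append(record)

    results = pd.DataFrame(rows)
    ok = results[results["error"].isna()] if results["error"].notna().any() \
        else results
    summary = pd.DataFrame(index=sorted({m.get("base_level") or base_rank
                                         for m in methods}),
                           columns=[_method_label(m) for m in methods], dtype=object)
    for (lvl, label), grp in ok.groupby(["base_level", "method"]):
        mean_err = grp["mse"].mean()
        # round-half-even on the mean sparsity, as in standard summary tables
        sparsity = round(float(grp["n_selected"].mean()))
        summary.loc[lvl, label] = f"{mean_err:.4g} ({sparsity})"

    rank_rows = {}
    for label, fits in fits_by_method.items():
        rank_rows[label] = rank_selection_summary(fits, ranks=tree.ranks)
    rank_summary = pd.DataFrame(rank_rows).T if rank_rows else pd.DataFrame()

    return BenchmarkTable(results=results, summary=summary,
                          rank_summary=rank_summary, n_excluded=n_excluded)
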