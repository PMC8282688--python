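"""Readers and writers for count tables, taxonomies, and responses.

Plain TSV/CSV are the interchange formats; all joins are by identifier,
never by position, so files survive row/column reordering.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CountTable
from .model import TracFit
from .selection import CVResult
from .taxonomy import Lineage, TaxTree, parse_lineages


@dataclass
class RunConfig:
    """Resolved run parameters, serialized alongside every output."""

    pseudocount: float = 1.0
    a: float = 1.0
    n_lambda: int = 50
    min_fraction: float = 1e-3
    cv_folds: int = 5
    selection_rule: str = "1se"
    seed: int = 0
    base_level: str | None = None
    orientation: str = "samples_by_taxa"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_rule not in {"1se", "min"}:
            raise ValueError("selection_rule must be '1se' or 'min'")
        if self.orientation not in {"samples_by_taxa", "taxa_by_samples"}:
            raise ValueError("unknown orientation")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def atomic_write(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_counts(path: str | Path, orientation: str = "samples_by_taxa") -> CountTable:
    """Read a counts TSV/CSV: first column sample ids, header taxon ids.

    ``orientation="taxa_by_samples"`` accepts the transposed dialect.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "taxa_by_samples":
        df = df.T
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [
            f"line {i + 2}"  # +1 header, +1 one-based
            for i, row in enumerate(df.itertuples(index=False))
            if any(not _is_number(v) for v in row)
        ]
        raise ValueError(f"non-numeric counts in {path} ({', '.join(bad[:5])})") from exc
    return CountTable(X, [str(s) for s in df.index], [str(t) for t in df.columns])


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_counts(counts: CountTable, path: str | Path) -> None:
    df = pd.DataFrame(counts.X, index=counts.sample_ids, columns=counts.taxon_ids)
    atomic_write(path, df.to_csv(sep=_sep(path)))


def read_taxonomy(
    path: str | Path,
    taxon_id_column: str = "taxon_id",
    lineage_column: str | None = None,
    strip_prefixes: bool = True,
) -> TaxTree:
    """Read a taxonomy table and build the tree.

    Either one column per rank (all non-id columns, in file order), or a
    single semicolon-separated lineage string column in the
    ``k__Bacteria;p__...`` dialect (rank prefixes stripped when requested).
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if taxon_id_column not in df.columns:
        raise ValueError(f"taxonomy file lacks a {taxon_id_column!r} column")
    rows: list[Lineage] = []
    if lineage_column is not None:
        prefixes = "kpcofgs"
        for _, rec in df.iterrows():
            parts = [p.strip() for p in str(rec[lineage_column]).split(";")]
            if strip_prefixes:
                parts = [
                    p[3:] if len(p) > 3 and p[1:3] == "__" and p[0] in prefixes else p
                    for p in parts
                ]
            ranks = [f"rank{i + 1}" for i in range(len(parts))]
            rows.append(Lineage(str(rec[taxon_id_column]),
                                tuple(zip(ranks, parts))))
    else:
        rank_cols = [c for c in df.columns if c != taxon_id_column]
        if not rank_cols:
            raise ValueError("taxonomy file has no rank columns")
        for _, rec in df.iterrows():
            rows.append(Lineage(
                str(rec[taxon_id_column]),
                tuple((c, rec[c]) for c in rank_cols),
            ))
    return parse_lineages(rows)


def write_taxonomy(tree: TaxTree, path: str | Path) -> None:
    recs = []
    for ln in tree.lineages:
        rec = {"taxon_id": ln.taxon_id}
        rec.update({r: n for r, n in ln.ranked_names})
        recs.append(rec)
    df = pd.DataFrame(recs)
    atomic_write(path, df.to_csv(sep=_sep(path), index=False))


def read_response(path: str | Path, value_column: str | None = None) -> pd.Series:
    """Read a per-sample response CSV: first column sample id."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if value_column is None:
        value_column = df.columns[0]
    s = df[value_column].astype(float)
    if s.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return s


def read_dataset(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    response_path: str | Path | None = None,
    cfg: RunConfig | None = None,
) -> tuple[CountTable, TaxTree, np.ndarray | None]:
    """Load and align counts, taxonomy, and (optionally) response.

    Samples are joined on id (order-insensitive); taxa present in the counts
    but absent from the taxonomy, or samples without a response value, are
    reported by name.
    """
    cfg = cfg or RunConfig()
    counts = read_counts(counts_path, cfg.orientation)
    tree = read_taxonomy(taxonomy_path)
    missing_taxa = [t for t in counts.taxon_ids if t not in set(tree.leaf_ids)]
    if missing_taxa:
        raise ValueError(f"taxa in counts absent from taxonomy: {missing_taxa[:10]}")
    counts = counts.reorder_taxa(list(tree.leaf_ids))
    y = None
    if response_path is not None:
        s = read_response(response_path)
        missing = [sid for sid in counts.sample_ids if sid not in s.index]
        if missing:
            raise ValueError(f"samples without a response value: {missing[:10]}")
        y = s.loc[counts.sample_ids].to_numpy()
    return counts, tree, y


def write_selected_aggregations(fit: TracFit, path: str | Path) -> None:
    """TSV of nonzero aggregations (taxon, level, alpha, path), |alpha| desc."""
    atomic_write(path, fit.selected.to_csv(sep="\t", index=False))


def read_selected_aggregations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cv_curve(cv: CVResult, path: str | Path) -> None:
    atomic_write(path, cv.to_frame().to_csv(sep="\t", index=False))


def save_model(fit: TracFit, path: str | Path) -> None:
    atomic_write(path, fit.to_json())


def load_model(path: str | Path) -> TracFit:
    return TracFit.from_json(Path(path).read_text())
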