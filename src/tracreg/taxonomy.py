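"""Rooted taxonomic trees built from lineage annotations.

A taxonomy assigns every base-level taxon (OTU/ASV) a lineage across ordered
ranks (Kingdom, Phylum, ..., Genus, OTU).  The tree :class:`TaxTree` collects
those lineages under a single artificial root node ("Life"), so that even the
top rank is a selectable aggregation level.  Node identity is the full path
from the root joined by ``::``; bare rank names are display labels only,
because identical genus/family names recur in unrelated clades.

The key structural object for modeling is the binary ancestry matrix ``A``
(leaves x non-root nodes) with ``A[j, u] = 1`` iff leaf ``j`` lies in the
subtree rooted at ``u``; its column sums are the subtree leaf counts
``|L_u|`` that drive both feature aggregation and the penalty weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

SEP = "::"
ROOT_NAME = "Life"
UNCLASSIFIED = "unclassified"

#: strings treated as a missing name at a rank
_MISSING = {"", "na", "n/a", "nan", "none", "null", "unclassified", "uncultured"}


@dataclass(frozen=True)
class Lineage:
    """Lineage of one base-level taxon, ordered coarsest to finest rank."""

    taxon_id: str
    ranked_names: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.ranked_names:
            raise ValueError(f"lineage for {self.taxon_id!r} has no ranks")


def _clean_name(name: object) -> str | None:
    if name is None:
        return None
    s = str(name).strip()
    if s.lower() in _MISSING:
        return None
    return s


@dataclass
class TaxTree:
    """Rooted taxonomy with per-node subtree leaf sets.

    ``nodes`` lists every node (root included) in depth-first preorder with
    children visited in lexicographic order; ``column_order`` (the non-root
    nodes in that same order) indexes coefficient vectors throughout the
    package.  ``leaves`` keeps the input order of the count-table columns.
    """

    root: str
    parent: dict[str, str]
    children: dict[str, list[str]]
    leaves: list[str]
    leaf_ids: list[str]
    leaf_sets: dict[str, np.ndarray]
    node_rank: dict[str, str]
    ranks: tuple[str, ...]
    lineages: list[Lineage] = field(repr=False, default_factory=list)

    # -- derived orderings -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(self.children.get(u, [])))
        return out

    @property
    def column_order(self) -> list[str]:
        return [u for u in self.nodes if u != self.root]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def display_name(self, node: str) -> str:
        return node.rsplit(SEP, 1)[-1]

    def depth(self, node: str) -> int:
        """Number of edges from the root."""
        d = 0
        while node != self.root:
            node = self.parent[node]
            d += 1
        return d

    def rank_nodes(self, rank: str) -> list[str]:
        if rank not in self.ranks:
            raise ValueError(f"rank {rank!r} not in taxonomy ranks {self.ranks}")
        return [u for u in self.nodes if self.node_rank.get(u) == rank]

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def validate(self) -> None:
        roots = [u for u in self.nodes if u not in self.parent]
        if roots != [self.root]:
            raise ValueError("tree must have exactly one root")
        all_leaves = self.leaf_sets[self.root]
        if len(all_leaves) != len(self.leaves):
            raise ValueError("root leaf set must cover all leaves")
        for u in self.nodes:
            kids = self.children.get(u, [])
            if kids:
                merged = np.sort(np.concatenate([self.leaf_sets[c] for c in kids]))
                if len(np.unique(merged)) != len(merged) or not np.array_equal(
                    merged, np.sort(self.leaf_sets[u])
                ):
                    raise ValueError(
                        f"leaf set of {u!r} is not the disjoint union of its children"
                    )
            else:
                if len(self.leaf_sets[u]) != 1:
                    raise ValueError(f"leaf {u!r} must have a singleton leaf set")


def parse_lineages(rows: list[Lineage]) -> TaxTree:
    """Build a :class:`TaxTree` from per-taxon lineages.

    All rows must share one ordered rank list and have unique taxon ids.
    Missing names at a rank are replaced by an ``unclassified`` placeholder
    scoped to the parent path, so unannotated clades under different parents
    stay distinct.  Leaves are kept in input order.
    """
    if not rows:
        raise ValueError("no lineages given")
    ranks = tuple(r for r, _ in rows[0].ranked_names)
    ids = [row.taxon_id for row in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate taxon_id(s): {dupes}")

    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {ROOT_NAME: []}
    node_rank: dict[str, str] = {ROOT_NAME: "root"}
    leaves: list[str] = []

    for row in rows:
        if tuple(r for r, _ in row.ranked_names) != ranks:
            raise ValueError(
                f"inconsistent rank ordering for {row.taxon_id!r}: expected {ranks}"
            )
        path = ROOT_NAME
        for rank, raw in row.ranked_names:
            name = _clean_name(raw)
            if name is None:
                name = UNCLASSIFIED
            child = path + SEP + name
            if child not in parent:
                parent[child] = path
                children.setdefault(path, []).append(child)
                children.setdefault(child, [])
                node_rank[child] = rank
            elif node_rank[child] != rank:
                raise ValueError(
                    f"node {child!r} appears at ranks {node_rank[child]!r} and {rank!r}"
                )
            path = child
        if path in leaves:
            raise ValueError(
                f"two taxa share the full lineage {path!r}; include the taxon id "
                "as the base rank to disambiguate"
            )
        if children[path]:
            raise ValueError(f"base-level node {path!r} is an ancestor of another taxon")
        leaves.append(path)

    for kids in children.values():
        kids.sort()

    # bottom-up leaf sets
    leaf_index = {leaf: j for j, leaf in enumerate(leaves)}
    leaf_sets: dict[str, np.ndarray] = {}

    def _collect(u: str) -> np.ndarray:
        kids = children.get(u, [])
        if not kids:
            arr = np.array([leaf_index[u]], dtype=np.intp)
        else:
            arr = np.sort(np.concatenate([_collect(c) for c in kids]))
        leaf_sets[u] = arr
        return arr

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * (len(ranks) + 3)))
    try:
        _collect(ROOT_NAME)
    finally:
        sys.setrecursionlimit(old)

    tree = TaxTree(
        root=ROOT_NAME,
        parent=parent,
        children=children,
        leaves=leaves,
        leaf_ids=ids,
        leaf_sets=leaf_sets,
        node_rank=node_rank,
        ranks=ranks,
        lineages=list(rows),
    )
    tree.validate()
    return tree


@dataclass
class AncestryMatrix:
    """Binary leaf-by-node ancestry indicator ``A`` (CSR sparse)."""

    A: sparse.csr_array
    column_order: list[str]
    leaf_order: list[str]

    def toarray(self) -> np.ndarray:
        return self.A.toarray()


def ancestry_matrix(tree: TaxTree) -> AncestryMatrix:
    """Return ``A`` with ``A[j, u] = 1`` iff leaf ``j`` is in subtree ``u``.

    Columns follow the tree's depth-first column order; rows follow the leaf
    (count-table column) order.
    """
    cols = tree.column_order
    p = tree.n_leaves
    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    for k, u in enumerate(cols):
        members = tree.leaf_sets[u]
        rows_idx.append(members)
        cols_idx.append(np.full(len(members), k, dtype=np.intp))
    data = np.ones(sum(len(r) for r in rows_idx))
    A = sparse.csr_array(
        (data, (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(p, len(cols)),
    )
    return AncestryMatrix(A=A, column_order=cols, leaf_order=list(tree.leaves))


def leaf_counts(tree: TaxTree) -> dict[str, int]:
    """Subtree leaf counts ``|L_u|`` for every node (root included)."""
    return {u: len(tree.leaf_sets[u]) for u in tree.nodes}


def truncated_lineages(tree: TaxTree, rank: str) -> list[Lineage]:
    """Lineages cut at ``rank``, one per rank-level node, for re-rooting a
    coarser base level (taxon_id = full node path)."""
    if rank not in tree.ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy ranks {tree.ranks}")
    keep = tree.ranks[: tree.ranks.index(rank) + 1]
    out: list[Lineage] = []
    seen: set[str] = set()
    for u in tree.nodes:
        if tree.node_rank.get(u) == rank and u not in seen:
            seen.add(u)
            parts = u.split(SEP)[1:]  # drop root
            out.append(Lineage(taxon_id=u, ranked_names=tuple(zip(keep, parts))))
    return out
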