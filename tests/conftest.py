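import numpy as np
import pytest

from tracreg import CountTable, Lineage, parse_lineages
from tracreg.solver import TracProblem


@pytest.fixture
def three_leaf_tree():
    """One kingdom, two families, three genera: {B;F1;G1, B;F1;G2, B;F2;G3}."""
    rows = [
        Lineage("G1", (("Kingdom", "B"), ("Family", "F1"), ("Genus", "G1"))),
        Lineage("G2", (("Kingdom", "B"), ("Family", "F1"), ("Genus", "G2"))),
        Lineage("G3", (("Kingdom", "B"), ("Family", "F2"), ("Genus", "G3"))),
    ]
    return parse_lineages(rows)


@pytest.fixture
def star_tree4():
    rows = [Lineage(t, (("OTU", t),)) for t in ["t1", "t2", "t3", "t4"]]
    return parse_lineages(rows)


@pytest.fixture
def balanced_tree4():
    """Root -> two internal nodes -> two leaves each."""
    rows = [
        Lineage("a1", (("Family", "A"), ("OTU", "a1"))),
        Lineage("a2", (("Family", "A"), ("OTU", "a2"))),
        Lineage("b1", (("Family", "B"), ("OTU", "b1"))),
        Lineage("b2", (("Family", "B"), ("OTU", "b2"))),
    ]
    return parse_lineages(rows)


@pytest.fixture
def chain_tree():
    return parse_lineages(
        [Lineage("G1", (("Kingdom", "B"), ("Family", "F1"), ("Genus", "G1")))]
    )


def random_problem(rng, n=30, m=8, a=1.0, leaf_count_max=8):
    """Random solver instance with |L|^-a-style weights."""
    Z = rng.normal(size=(n, m))
    y = rng.normal(size=n)
    sizes = rng.integers(1, leaf_count_max + 1, size=m).astype(float)
    w = sizes ** (-a)
    return TracProblem(y=y, Z=Z, w=w, fit_intercept=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_counts(rng, tree, n=12, lam=30.0):
    p = tree.n_leaves
    X = rng.poisson(lam, size=(n, p)).astype(float) + 1.0
    return CountTable(X, [f"s{i}" for i in range(n)], list(tree.leaf_ids))
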