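import numpy as np
import pytest

import radsplit as rs
from radsplit.trees import tree_from_newick


@pytest.fixture(scope="session")
def jc():
    return rs.SubstitutionModel()


@pytest.fixture(scope="session")
def gtr_ig():
    return rs.SubstitutionModel(
        family="GTR",
        base_freqs=(0.3, 0.2, 0.2, 0.3),
        exchangeabilities=(1.2, 3.0, 0.8, 1.1, 4.0, 1.0),
        p_inv=0.2,
        alpha=0.6,
    )


@pytest.fixture(scope="session")
def four_taxon_tree():
    return tree_from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);")


@pytest.fixture(scope="session")
def four_taxon_alignment():
    return rs.Alignment(("A", "B", "C", "D"), ("ACGTA", "ACGTC", "AGGT-", "ACTTR"))


def random_alignment(rng: np.random.Generator, n_taxa: int, n_cols: int,
                     missing: float = 0.0) -> rs.Alignment:
    """Uniform random alignment (optionally with missing characters)."""
    chars = np.array(list("ACGT"))
    rows = chars[rng.integers(0, 4, size=(n_taxa, n_cols))]
    if missing > 0:
        mask = rng.random((n_taxa, n_cols)) < missing
        rows[mask] = "-"
    labels = tuple(f"t{i}" for i in range(n_taxa))
    return rs.Alignment(labels, tuple("".join(r) for r in rows))


def random_tree(rng: np.random.Generator, labels, with_lengths: bool = True):
    """Random binary topology by sequential leaf attachment."""
    from radsplit.parsimony import (
        _insert_leaf,
        _insertable_edges,
        _node_path,
        _three_taxon_tree,
    )

    labels = list(labels)
    rng.shuffle(labels)
    tree = _three_taxon_tree(*labels[:3])
    for name in labels[3:]:
        edges = _insertable_edges(tree)
        edge = edges[rng.integers(0, len(edges))]
        tree = _insert_leaf(tree, _node_path(tree, edge), name)
    if with_lengths:
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.01, 0.5))
    return tree
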