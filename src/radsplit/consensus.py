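"""Bipartition tallies, majority-rule consensus, and bootstrap support."""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np

from .njoin import nj_tree
from .seqchar import pairwise_distance_matrix
from .seqio import Alignment
from .trees import Node, Tree, TreeError, bipartition

__all__ = [
    "bipartition_counts",
    "majority_rule_consensus",
    "bootstrap_support",
    "same_unrooted_topology",
]


def same_unrooted_topology(a: Tree, b: Tree) -> bool:
    """True iff the two trees share leaf set and full bipartition set."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return a.bipartitions() == b.bipartitions()


def bipartition_counts(trees: Sequence[Tree]) -> tuple[Counter, frozenset]:
    if not trees:
        raise TreeError("no trees to tally")
    universe = frozenset(trees[0].leaf_names())
    counts: Counter = Counter()
    for t in trees:
        if frozenset(t.leaf_names()) != universe:
            raise TreeError("trees are on different label sets")
        counts.update(t.bipartitions())
    return counts, universe


def majority_rule_consensus(trees: Sequence[Tree], cutoff: float = 0.5) -> Tree:
    """Consensus keeping bipartitions with frequency > ``cutoff`` (default
    50% majority rule), each annotated with its frequency as support.

    With ``cutoff >= 0.5`` retained splits are pairwise compatible by
    counting; below 0.5, incompatible splits are skipped greedily in
    decreasing frequency order.
    """
    counts, universe = bipartition_counts(trees)
    n = len(trees)
    ref = min(universe)
    kept: list[tuple[frozenset, float]] = []
    for split, cnt in sorted(
        counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
    ):
        freq = cnt / n
        if freq <= cutoff:
            continue
        side = split  # canonical side excludes the reference taxon
        if all(side <= s or s <= side or not (side & s) for s, _ in kept):
            kept.append((side, freq))
    # build: nest sides (a laminar family) under the star over the universe
    kept.sort(key=lambda sf: -len(sf[0]))
    root = Node()
    owner: dict[frozenset, Node] = {side: Node(support=freq) for side, freq in kept}
    # attach each split node under its smallest strict superset
    for side, _ in kept:
        parents = [s for s, _ in kept if side < s]
        parent = owner[min(parents, key=len)] if parents else root
        parent.add_child(owner[side])
    for leaf_name in sorted(universe):
        hosts = [s for s, _ in kept if leaf_name in s]
        parent = owner[min(hosts, key=len)] if hosts else root
        parent.add_child(Node(leaf_name))
    return Tree(root)


def _infer_one(
    alignment: Alignment,
    method: str,
    seed: int,
    model=None,
    nj_metric: str = "p_distance",
    thorough: bool = False,
) -> Tree:
    # canonical row order so results never depend on taxon input order
    order = sorted(alignment.labels)
    if list(alignment.labels) != order:
        alignment = alignment.subset(order)
    if method == "nj":
        d = pairwise_distance_matrix(alignment, nj_metric)
        return nj_tree(d, alignment.labels)
    if method == "mp":
        from .parsimony import parsimony_search

        # point estimates get a fuller search than bootstrap replicates
        tree, _ = parsimony_search(
            alignment, n_random_starts=5 if thorough else 1, seed=seed
        )
        return tree
    if method == "ml":
        from .likelihood import nni_search

        if model is None:
            raise ValueError("ml bootstrap needs a substitution model")
        d = pairwise_distance_matrix(alignment, nj_metric)
        start = nj_tree(d, alignment.labels)
        tree, _ = nni_search(start, alignment, model)
        return tree
    raise ValueError(f"unknown inference method {method!r}")


def bootstrap_support(
    alignment: Alignment,
    method: str = "mp",
    replicates: int = 100,
    seed: int = 0,
    model=None,
    nj_metric: str = "p_distance",
    point_tree: Optional[Tree] = None,
) -> Tree:
    """Nonparametric bootstrap: resample columns with replacement, infer per
    replicate, and annotate the point-estimate tree's internal edges with
    the fraction of replicates containing each bipartition.

    Replicate seeds derive deterministically from the master ``seed``.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates + 1)]
    if point_tree is None:
        point_tree = _infer_one(
            alignment, method, child_seeds[0], model, nj_metric, thorough=True
        )
    rng = np.random.default_rng(child_seeds[0])
    counts: Counter = Counter()
    n_cols = alignment.n_cols
    for b in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = alignment.columns(list(idx))
        tree = _infer_one(rep, method, child_seeds[b + 1], model, nj_metric)
        counts.update(tree.bipartitions())
    out = point_tree.copy()
    splits = out.bipartitions(with_nodes=True)
    for split, node in splits.items():
        node.support = counts.get(split, 0) / replicates
    return out
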