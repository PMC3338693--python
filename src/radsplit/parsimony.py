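"""Fitch parsimony scoring and heuristic/exhaustive MP tree search.

Characters are bitmask-encoded (A=1, C=2, G=4, T=8; ambiguity codes are
unions; gaps and ``?`` carry the full state set, i.e. missing data never
costs a step). The heuristic search is random stepwise addition followed by
NNI branch swapping; trees on at most 7 taxa are searched exhaustively.
Score ties are broken by the lexicographically smallest canonical newick,
so results are deterministic given the seed.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np

from .likelihood import canonical_newick, nni_neighbors, root_at_leaf
from .seqio import AMBIGUITY, Alignment
from .trees import Node, Tree

__all__ = [
    "FitchData",
    "fitch_score",
    "parsimony_search",
    "all_topologies",
]

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


def _mask_of(ch: str) -> int:
    return sum(_BIT[s] for s in AMBIGUITY[ch])


class FitchData:
    """Compressed site patterns as per-taxon bitmask arrays."""

    def __init__(self, alignment: Alignment):
        mat = np.frombuffer("".join(alignment.rows).encode(), dtype="S1").reshape(
            alignment.n_taxa, alignment.n_cols
        )
        patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
        patterns = patterns.T
        self.weights = counts.astype(np.int64)
        lut = np.zeros(256, dtype=np.uint8)
        for ch in AMBIGUITY:
            lut[ord(ch)] = _mask_of(ch)
        self.masks = {
            label: lut[patterns[i].view(np.uint8)]
            for i, label in enumerate(alignment.labels)
        }


def fitch_score(tree: Tree, data) -> int:
    """Weighted Fitch parsimony length of ``tree`` (unrooted score; the
    degree-2 root adds no step)."""
    if isinstance(data, Alignment):
        data = FitchData(data)
    score = np.int64(0)
    states: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states[id(node)] = data.masks[node.name]
            continue
        acc = states[id(node.children[0])]
        for child in node.children[1:]:
            other = states[id(child)]
            inter = acc & other
            union = acc | other
            miss = inter == 0
            score += data.weights[miss].sum()
            acc = np.where(miss, union, inter)
        states[id(node)] = acc
    return int(score)


# ---------------------------------------------------------------------------
# topology generation
# ---------------------------------------------------------------------------

def _insertable_edges(tree: Tree) -> list[Node]:
    """Nodes below every distinct unrooted edge of a rooted-at-leaf tree.

    The root's two half-edges describe one pendant edge; only the non-anchor
    half is listed.
    """
    anchor = tree.root.children[0]
    return [n for n in tree.postorder() if n.parent is not None and n is not anchor]


def _insert_leaf(tree: Tree, edge_node_path: tuple[int, ...], name: str) -> Tree:
    new = tree.copy()
    node = new.root
    for i in edge_node_path:
        node = node.children[i]
    parent = node.parent
    idx = parent.children.index(node)
    mid = Node()
    mid.add_child(node)
    mid.add_child(Node(name))
    mid.parent = parent
    parent.children[idx] = mid
    return Tree(new.root)


def _node_path(tree: Tree, node: Node) -> tuple[int, ...]:
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return tuple(reversed(path))


def _three_taxon_tree(a: str, b: str, c: str) -> Tree:
    root = Node()
    root.add_child(Node(a))
    inner = Node()
    inner.add_child(Node(b))
    inner.add_child(Node(c))
    root.add_child(inner)
    return Tree(root)


def all_topologies(labels: Sequence[str]) -> Iterator[Tree]:
    """Every unrooted binary topology on ``labels`` ((2n-5)!! trees),
    generated by sequential leaf insertion in a fixed order."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    stack = [(_three_taxon_tree(*labels[:3]), 3)]
    while stack:
        tree, k = stack.pop()
        if k == len(labels):
            yield tree
            continue
        for edge in _insertable_edges(tree):
            stack.append((_insert_leaf(tree, _node_path(tree, edge), labels[k]), k + 1))


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _stepwise_addition(
    labels: Sequence[str], data: FitchData, rng: np.random.Generator
) -> Tree:
    order = list(labels)
    rng.shuffle(order)
    tree = _three_taxon_tree(*sorted(order[:3]))
    for name in order[3:]:
        best: Optional[tuple[int, Tree]] = None
        ties: list[Tree] = []
        for edge in _insertable_edges(tree):
            cand = _insert_leaf(tree, _node_path(tree, edge), name)
            s = fitch_score(cand, data)
            if best is None or s < best[0]:
                best = (s, cand)
                ties = [cand]
            elif s == best[0]:
                ties.append(cand)
        tree = (
            min(ties, key=canonical_newick) if len(ties) > 1 else best[1]
        )
    return tree


def _nni_refine(tree: Tree, data: FitchData, max_rounds: int = 100) -> tuple[Tree, int]:
    tree = root_at_leaf(tree)
    score = fitch_score(tree, data)
    for _ in range(max_rounds):
        best_score = score
        ties: list[Tree] = []
        for cand in nni_neighbors(tree):
            s = fitch_score(cand, data)
            if s < best_score:
                best_score = s
                ties = [cand]
            elif s == best_score and s < score:
                ties.append(cand)
        if best_score >= score:
            break
        tree = min(ties, key=canonical_newick) if len(ties) > 1 else ties[0]
        score = best_score
    return tree, score


def parsimony_search(
    alignment: Alignment,
    n_random_starts: int = 10,
    seed: int = 0,
) -> tuple[Tree, int]:
    """Best MP tree and its Fitch length.

    Random stepwise-addition starts refined by NNI swapping; exhaustive
    enumeration replaces the heuristic for <=7 taxa. Returned trees carry
    no branch lengths (parsimony estimates topology only).
    """
    if alignment.n_taxa < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    data = FitchData(alignment)
    labels = list(alignment.labels)
    if alignment.n_taxa <= 7:
        best: Optional[tuple[int, str, Tree]] = None
        for tree in all_topologies(labels):
            s = fitch_score(tree, data)
            key = (s, canonical_newick(tree))
            if best is None or key < (best[0], best[1]):
                best = (s, key[1], tree)
        return best[2], best[0]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_random_starts):
        start = _stepwise_addition(labels, data, rng)
        tree, score = _nni_refine(start, data)
        key = (score, canonical_newick(tree))
        if best is None or key < (best[0], best[1]):
            best = (score, key[1], tree)
    return best[2], best[0]
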