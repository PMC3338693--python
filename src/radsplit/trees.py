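"""Lightweight rooted-tree container shared by every stage of the pipeline.

The tree is stored rooted (a degree-2 root node represents an unrooted
binary tree), with optional branch lengths (``None`` means *unknown*, never
zero) and optional per-internal-node support values on the 0-1 scale.
Bipartitions — the unit of all congruence and consensus bookkeeping — are
canonicalized as the side of the split that excludes the lexicographically
smallest taxon of the universe, so complementation never produces two
distinct keys for one edge.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "bipartition",
    "tree_from_newick",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, sup={self.support})"


class Tree:
    """A rooted tree over uniquely labeled leaves."""

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf labels: {dups}")

    # ------------------------------------------------------------------ walks
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    # ------------------------------------------------------------- predicates
    def is_binary(self) -> bool:
        """True if every internal node has 2 children (root included)."""
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def n_leaves(self) -> int:
        return len(self.leaves())

    # ---------------------------------------------------------------- copying
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    # ----------------------------------------------------------- bipartitions
    def bipartitions(
        self, with_nodes: bool = False
    ) -> dict[frozenset, Optional[Node]] | set[frozenset]:
        """Non-trivial splits of the unrooted version of this tree.

        Returns canonical bipartitions (see :func:`bipartition`).  With
        ``with_nodes=True`` a dict mapping each split to the child node of
        the edge inducing it (the deeper of the two root-adjacent nodes for
        the split through the root).
        """
        universe = frozenset(self.leaf_names())
        below: dict[int, frozenset] = {}
        result: dict[frozenset, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                side = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = side
            if node is self.root or node.parent is None:
                continue
            side = below[id(node)]
            if 1 < len(side) < len(universe) - 1:
                key = bipartition(side, universe)
                # keep the first (deepest) node seen for the root split:
                # both root-adjacent edges induce the same bipartition and
                # must agree, so either representative is fine.
                result.setdefault(key, node)
        if with_nodes:
            return result
        return set(result)

    # --------------------------------------------------------------- rooting
    def reroot_at_edge(self, node: Node) -> "Tree":
        """Return a copy rerooted on the edge above ``node`` (midpoint-less:
        the old branch length is kept entirely on ``node``'s side)."""
        if node is self.root:
            return self.copy()
        # Work on a copy; find the corresponding node via a path signature.
        path = []
        cur = node
        while cur.parent is not None:
            path.append(cur.parent.children.index(cur))
            cur = cur.parent
        new = self.copy()
        cur = new.root
        for idx in reversed(path):
            cur = cur.children[idx]
        return Tree(_reroot(new.root, cur))

    # ---------------------------------------------------------------- newick
    def to_newick(
        self,
        include_support: bool = True,
        include_lengths: bool = True,
        support_format: Callable[[float], str] = lambda s: f"{s:.6g}",
    ) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if include_support and node.support is not None:
                    label += support_format(node.support)
            if include_lengths and node.length is not None:
                label += f":{node.length:.12g}"
            return label

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree<{self.n_leaves()} leaves>"


def bipartition(side, universe) -> frozenset:
    """Canonical form of the split ``side | universe-side``: the half that
    does NOT contain the lexicographically smallest taxon."""
    side = frozenset(side)
    universe = frozenset(universe)
    if not side or not side < universe:
        raise TreeError("bipartition side must be a nonempty proper subset")
    ref = min(universe)
    return universe - side if ref in side else side


def _reroot(old_root: Node, new_child: Node) -> Node:
    """Re-hang a (mutable) tree so the edge above ``new_child`` carries a new
    degree-2 root. Supports are kept attached to the same bipartitions."""
    # Collect path from new_child up to old root.
    path = []
    cur = new_child
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    new_root = Node()
    length = new_child.length
    new_child.parent = None
    new_child.length = 0.0 if length is None else length / 2.0
    new_root.add_child(new_child)
    # Reverse parent links along the path.
    prev = new_root
    prev_len = 0.0 if length is None else length / 2.0
    for i in range(1, len(path)):
        node = path[i]
        child_on_path = path[i - 1]
        if child_on_path in node.children:
            node.children.remove(child_on_path)
        node.parent = None
        carried_len = node.length
        node.length = prev_len
        prev_len = carried_len
        if len(node.children) == 1 and node is path[-1]:
            # old degree-2 root collapses away; its two half-edges merge
            orphan = node.children[0]
            orphan.parent = None
            if orphan.length is not None and node.length is not None:
                orphan.length = orphan.length + node.length
            prev.add_child(orphan)
        else:
            prev.add_child(node)
            prev = node
    return new_root


def tree_from_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Numeric internal-node labels are read as supports and rescaled to [0,1]
    (values > 1 are divided by 100, the usual bootstrap-percentage
    convention). Missing branch lengths stay ``None``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("leaf without a label")
            node = Node(dnode.taxon.label, dnode.edge.length)
        else:
            support = None
            label = dnode.label
            if label is not None:
                try:
                    support = float(label)
                except ValueError:
                    support = None
            if support is not None and support > 1.0:
                support /= 100.0
            node = Node(None, dnode.edge.length, support)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    tree = Tree(convert(dtree.seed_node))
    return tree
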