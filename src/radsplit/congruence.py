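"""Gene-performance assessment: congruent-node scoring against a reference
tree, ranking and good/medium/poor classification.

A reference node is an internal bipartition of the combined-data tree
separating at least two ingroup taxa from the rest. A gene tree recovers
("is congruent with") a node iff the node's bipartition, restricted to the
taxa the two trees share, occurs among the gene tree's bipartitions;
recovered nodes are stratified by the gene tree's support on that edge
(strong at or above the threshold, weak below — edges without a support
value count as weak).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .trees import Tree, TreeError, bipartition

__all__ = [
    "ReferenceNodeSet",
    "GenePerformance",
    "reference_nodes",
    "score_gene",
    "rank_genes",
]


@dataclass(frozen=True)
class ReferenceNodeSet:
    reference_tree: Tree
    nodes: tuple[tuple[int, frozenset], ...]  # (node_id, canonical bipartition)
    outgroup: frozenset

    def __post_init__(self):
        ids = [i for i, _ in self.nodes]
        if len(ids) != len(set(ids)):
            raise TreeError("reference node ids must be unique")


@dataclass(frozen=True)
class GenePerformance:
    locus: str
    n_congruent_strong: int
    n_congruent_weak: int
    n_total: int
    recovered_ids: frozenset
    rank: Optional[int] = None
    performance_class: Optional[str] = None

    def __post_init__(self):
        if self.n_total != self.n_congruent_strong + self.n_congruent_weak:
            raise ValueError("n_total must equal strong + weak")
        if len(self.recovered_ids) != self.n_total:
            raise ValueError("recovered_ids size must equal n_total")


def reference_nodes(
    reference_tree: Tree,
    outgroup: Sequence[str],
    node_subset: Optional[Sequence[frozenset]] = None,
) -> ReferenceNodeSet:
    """Enumerate the scored reference nodes.

    Default: every internal bipartition whose ingroup side has >= 2 taxa,
    numbered 1..n in preorder. A ``node_subset`` (list of taxon sets, each
    one side of a split) overrides the default and fixes the ordering.
    """
    universe = frozenset(reference_tree.leaf_names())
    outgroup = frozenset(outgroup)
    missing = outgroup - universe
    if missing:
        raise TreeError(f"outgroup taxa not in the reference tree: {sorted(missing)}")
    ingroup = universe - outgroup
    splits = reference_tree.bipartitions()
    if node_subset is not None:
        nodes = []
        for i, side in enumerate(node_subset, 1):
            key = bipartition(side, universe)
            if key not in splits:
                raise TreeError(
                    f"node subset entry {i} is not a bipartition of the "
                    f"reference tree: {sorted(side)}"
                )
            nodes.append((i, key))
        return ReferenceNodeSet(reference_tree, tuple(nodes), outgroup)
    # preorder numbering over internal nodes inducing qualifying splits
    clade: dict[int, frozenset] = {}
    for node in reference_tree.postorder():
        clade[id(node)] = (
            frozenset([node.name])
            if node.is_leaf
            else frozenset().union(*(clade[id(c)] for c in node.children))
        )
    nodes = []
    next_id = 1
    for node in reference_tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        side = clade[id(node)]
        if not (1 < len(side) < len(universe) - 1):
            continue
        key = bipartition(side, universe)
        ingroup_side = min(side & ingroup, (universe - side) & ingroup, key=len)
        if len(ingroup_side) < 2:
            continue
        if any(key == k for _, k in nodes):
            continue  # the two root-adjacent edges induce one split
        nodes.append((next_id, key))
        next_id += 1
    return ReferenceNodeSet(reference_tree, tuple(nodes), outgroup)


def score_gene(
    gene_tree: Tree, refs: ReferenceNodeSet, threshold: float = 0.95, locus: str = ""
) -> GenePerformance:
    """Count reference nodes recovered by ``gene_tree``, split by support."""
    universe = frozenset(refs.reference_tree.leaf_names())
    gene_taxa = frozenset(gene_tree.leaf_names())
    shared = universe & gene_taxa
    ingroup = universe - refs.outgroup
    if not ingroup <= gene_taxa:
        raise TreeError(
            f"gene tree missing ingroup taxa: {sorted(ingroup - gene_taxa)}"
        )
    # gene splits restricted to the shared taxa, with their supports
    gene_splits: dict[frozenset, Optional[float]] = {}
    for split, node in gene_tree.bipartitions(with_nodes=True).items():
        side = split & shared
        if 1 < len(side) < len(shared) - 1:
            key = bipartition(side, shared)
            sup = node.support
            if key not in gene_splits:
                gene_splits[key] = sup
            else:
                prev = gene_splits[key]
                if prev is None or (sup is not None and sup > prev):
                    gene_splits[key] = sup
    strong = weak = 0
    recovered = []
    for node_id, ref_split in refs.nodes:
        side = ref_split & shared
        if not (1 < len(side) < len(shared) - 1):
            continue
        key = bipartition(side, shared)
        if key not in gene_splits:
            continue
        recovered.append(node_id)
        sup = gene_splits[key]
        if sup is not None and sup >= threshold:
            strong += 1
        else:
            weak += 1
    return GenePerformance(
        locus=locus,
        n_congruent_strong=strong,
        n_congruent_weak=weak,
        n_total=strong + weak,
        recovered_ids=frozenset(recovered),
    )


def rank_genes(
    performances: Sequence[GenePerformance], class_rule: str = "tertile"
) -> list[GenePerformance]:
    """Sort by total desc, strong desc, locus name; assign tertile classes
    on the total count (ties share the better class)."""
    if not performances:
        raise ValueError("no gene performances to rank")
    if class_rule != "tertile":
        raise ValueError(f"unknown class rule {class_rule!r}")
    ranked = sorted(
        performances,
        key=lambda p: (-p.n_total, -p.n_congruent_strong, p.locus),
    )
    n = len(ranked)
    totals = [p.n_total for p in ranked]
    good_cut = totals[(n + 2) // 3 - 1]
    med_cut = totals[(2 * n + 2) // 3 - 1]
    out = []
    for i, p in enumerate(ranked, 1):
        cls = "good" if p.n_total >= good_cut else (
            "medium" if p.n_total >= med_cut else "poor"
        )
        out.append(
            GenePerformance(
                locus=p.locus,
                n_congruent_strong=p.n_congruent_strong,
                n_congruent_weak=p.n_congruent_weak,
                n_total=p.n_total,
                recovered_ids=p.recovered_ids,
                rank=i,
                performance_class=cls,
            )
        )
    return out
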