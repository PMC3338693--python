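import numpy as np
import pytest

import radsplit as rs
from radsplit.congruence import (
    GenePerformance,
    rank_genes,
    reference_nodes,
    score_gene,
)
from radsplit.likelihood import nni_neighbors, root_at_leaf
from radsplit.trees import TreeError, bipartition, tree_from_newick

from conftest import random_tree


def _set_all_supports(tree, value):
    for node in tree.internal_nodes():
        if node.parent is not None:
            node.support = value
    return tree


class TestReferenceNodes:
    def test_caterpillar_with_outgroup(self):
        # 5 ingroup taxa on a caterpillar + 1 outgroup: the qualifying
        # splits isolate >=2 ingroup taxa on each side
        tree = tree_from_newick("((((A,B),C),(D,E)),OUT);")
        refs = reference_nodes(tree, outgroup=["OUT"])
        assert len(refs.nodes) == 3

    def test_star_ingroup_empty(self):
        tree = tree_from_newick("((A,B,C,D,E),OUT);")
        refs = reference_nodes(tree, outgroup=["OUT"])
        assert refs.nodes == ()

    def test_subset_override_order_preserved(self):
        tree = rs.build_species_tree(rs.SpeciesTreeSpec())
        default = reference_nodes(tree, outgroup=rs.synth.DEFAULT_OUTGROUP)
        assert len(default.nodes) >= 10
        subset = [split for _, split in default.nodes[:10]]
        subset = list(reversed(subset))
        override = reference_nodes(
            tree, outgroup=rs.synth.DEFAULT_OUTGROUP, node_subset=subset
        )
        assert len(override.nodes) == 10
        assert [s for _, s in override.nodes] == [
            bipartition(s, frozenset(tree.leaf_names())) for s in subset
        ]

    def test_subset_with_foreign_bipartition_rejected(self):
        tree = tree_from_newick("((((A,B),C),(D,E)),OUT);")
        with pytest.raises(TreeError):
            reference_nodes(tree, outgroup=["OUT"], node_subset=[{"A", "C"}])

    def test_missing_outgroup_taxon_rejected(self):
        tree = tree_from_newick("((A,B),(C,D));")
        with pytest.raises(TreeError):
            reference_nodes(tree, outgroup=["Z"])


class TestScoreGene:
    def test_reference_against_itself_recovers_everything(self):
        tree = _set_all_supports(
            tree_from_newick("(((((A,B),C),((D,E),F)),(G,H)),OUT);"), 1.0
        )
        refs = reference_nodes(tree, outgroup=["OUT"])
        perf = score_gene(tree, refs, threshold=0.95)
        assert perf.n_total == len(refs.nodes)
        assert perf.n_congruent_strong == len(refs.nodes)
        assert perf.recovered_ids == frozenset(i for i, _ in refs.nodes)

    def test_star_gene_tree_scores_zero(self):
        ref = _set_all_supports(tree_from_newick("((((A,B),C),(D,E)),OUT);"), 1.0)
        refs = reference_nodes(ref, outgroup=["OUT"])
        star = tree_from_newick("(A,B,C,D,E,OUT);")
        assert score_gene(star, refs).n_total == 0

    def test_support_stratification_and_missing_supports_weak(self):
        ref = tree_from_newick("(((((A,B),C),((D,E),F)),(G,H)),OUT);")
        refs = reference_nodes(ref, outgroup=["OUT"])
        gene = ref.copy()
        splits = gene.bipartitions(with_nodes=True)
        for i, (split, node) in enumerate(sorted(splits.items(), key=lambda kv: sorted(kv[0]))):
            node.support = 0.99 if i % 2 == 0 else 0.5
        perf = score_gene(gene, refs, threshold=0.95)
        assert perf.n_total == len(refs.nodes)
        assert perf.n_congruent_strong + perf.n_congruent_weak == perf.n_total
        assert perf.n_congruent_strong > 0 and perf.n_congruent_weak > 0
        # supports stripped entirely -> all weak
        bare = ref.copy()
        perf2 = score_gene(bare, refs, threshold=0.95)
        assert perf2.n_congruent_strong == 0
        assert perf2.n_total == len(refs.nodes)

    def test_table_pattern_seven_strong_one_weak_of_ten(self):
        """A gene tree recovering 8 of 10 scored nodes, 7 strongly."""
        ref = rs.build_species_tree(rs.SpeciesTreeSpec())
        all_nodes = reference_nodes(ref, outgroup=rs.synth.DEFAULT_OUTGROUP)
        subset = [split for _, split in all_nodes.nodes[:10]]
        refs = reference_nodes(ref, outgroup=rs.synth.DEFAULT_OUTGROUP, node_subset=subset)
        gene = ref.copy()
        by_split = gene.bipartitions(with_nodes=True)
        # recover nodes 1..8: first 7 strong, 8th weak; break nodes 9, 10
        for i, split in enumerate(subset, 1):
            node = by_split[split]
            if i <= 7:
                node.support = 0.99
            elif i == 8:
                node.support = 0.6
        for split in subset[8:]:
            node = by_split[split]
            # collapse the edge: splice children into the parent
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
        perf = score_gene(rs.Tree(gene.root), refs, threshold=0.95)
        assert (perf.n_congruent_strong, perf.n_congruent_weak, perf.n_total) == (7, 1, 8)
        assert perf.recovered_ids == frozenset(range(1, 9))

    def test_invariant_to_gene_tree_rooting(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)] + ["OUT"]
        ref = _set_all_supports(random_tree(rng, labels, with_lengths=False), 1.0)
        refs = reference_nodes(ref, outgroup=["OUT"])
        gene = _set_all_supports(random_tree(rng, labels, with_lengths=False), 0.99)
        base = score_gene(gene, refs)
        for leaf in gene.leaves():
            rerooted = gene.reroot_at_edge(leaf)
            alt = score_gene(rerooted, refs)
            assert (alt.n_total, alt.recovered_ids) == (base.n_total, base.recovered_ids)

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(1)
        labels = [f"t{i}" for i in range(7)] + ["OUT"]
        for _ in range(200):
            ref = random_tree(rng, labels, with_lengths=False)
            gene = _set_all_supports(random_tree(rng, labels, with_lengths=False), 1.0)
            refs = reference_nodes(ref, outgroup=["OUT"])
            perf = score_gene(gene, refs, threshold=0.95)
            gene_splits = gene.bipartitions()
            oracle = sum(1 for _, s in refs.nodes if s in gene_splits)
            assert perf.n_total == oracle

    def test_missing_ingroup_taxon_rejected(self):
        ref = tree_from_newick("((((A,B),C),(D,E)),OUT);")
        refs = reference_nodes(ref, outgroup=["OUT"])
        gene = tree_from_newick("(((A,B),C),(D,OUT));")
        with pytest.raises(TreeError, match="E"):
            score_gene(gene, refs)

    def test_random_nni_perturbation_never_helps_on_average(self):
        ref = _set_all_supports(
            tree_from_newick("(((((A,B),C),((D,E),F)),(G,H)),OUT);"), 1.0
        )
        refs = reference_nodes(ref, outgroup=["OUT"])
        base_total = score_gene(ref, refs).n_total
        rng = np.random.default_rng(2)
        totals = []
        for _ in range(100):
            perturbed = root_at_leaf(ref)
            for _ in range(2):
                neighbors = nni_neighbors(perturbed)
                perturbed = neighbors[rng.integers(0, len(neighbors))]
            totals.append(score_gene(_set_all_supports(perturbed, 1.0), refs).n_total)
        assert np.mean(totals) <= base_total


class TestRanking:
    def _perf(self, name, strong, weak):
        return GenePerformance(
            locus=name,
            n_congruent_strong=strong,
            n_congruent_weak=weak,
            n_total=strong + weak,
            recovered_ids=frozenset(range(strong + weak)),
        )

    def test_tertile_classes(self):
        ranked = rank_genes(
            [self._perf("a", 10, 0), self._perf("b", 8, 0), self._perf("c", 2, 0)]
        )
        assert [p.performance_class for p in ranked] == ["good", "medium", "poor"]

    def test_all_equal_totals_all_good(self):
        ranked = rank_genes([self._perf(n, 3, 1) for n in "abc"])
        assert all(p.performance_class == "good" for p in ranked)

    def test_ranking_is_a_permutation(self):
        rng = np.random.default_rng(3)
        perfs = [
            self._perf(f"g{i}", int(rng.integers(0, 5)), int(rng.integers(0, 5)))
            for i in range(20)
        ]
        ranked = rank_genes(perfs)
        assert sorted(p.locus for p in ranked) == sorted(p.locus for p in perfs)
        assert [p.rank for p in ranked] == list(range(1, 21))

    def test_sort_keys_total_then_strong_then_name(self):
        ranked = rank_genes(
            [self._perf("b", 2, 2), self._perf("a", 2, 2), self._perf("c", 4, 0)]
        )
        assert [p.locus for p in ranked] == ["c", "a", "b"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_genes([])
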