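import math

import numpy as np
import pytest

import radsplit as rs
from radsplit.seqio import concatenate
from radsplit.synth import (
    DEFAULT_TAXA,
    IntrogressionEvent,
    SimulationConfig,
    SpeciesTreeSpec,
    build_species_tree,
    default_introgression_event,
    expected_pairwise_coal_distance,
    generate_study,
    sample_gene_tree,
    simulate_alignment,
)
from radsplit.trees import TreeError, tree_from_newick


def clade_sets(tree):
    out = set()
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        names = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                names.add(n.name)
            stack.extend(n.children)
        out.add(frozenset(names))
    return out


class TestSpeciesTree:
    def test_default_is_binary_ultrametric_18_taxa(self):
        tree = build_species_tree(SpeciesTreeSpec())
        assert tree.n_leaves() == 18
        assert tree.is_binary()
        assert set(tree.leaf_names()) == set(DEFAULT_TAXA)

    def test_default_contains_study_clades(self):
        tree = build_species_tree(SpeciesTreeSpec())
        clades = clade_sets(tree)
        semno_trachy = frozenset(
            t for t in DEFAULT_TAXA
            if t.startswith(("Semnopithecus", "Trachypithecus"))
        )
        presbytis_oddnosed = frozenset(
            t for t in DEFAULT_TAXA
            if t.startswith(("Presbytis", "Pygathrix", "Rhinopithecus", "Nasalis"))
        )
        assert semno_trachy in clades
        assert presbytis_oddnosed in clades

    def test_two_taxon_cherry(self):
        spec = SpeciesTreeSpec(taxon_labels=("A", "B"), topology="(A:1,B:1);")
        tree = build_species_tree(spec)
        assert tree.n_leaves() == 2
        assert len(tree.internal_nodes()) == 1

    def test_duplicate_labels_rejected(self):
        spec = SpeciesTreeSpec(taxon_labels=("A", "A"), topology="(A:1,A:1);")
        with pytest.raises(TreeError):
            build_species_tree(spec)

    def test_non_binary_topology_rejected(self):
        spec = SpeciesTreeSpec(taxon_labels=("A", "B", "C"), topology="(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="binary"):
            build_species_tree(spec)

    def test_non_ultrametric_rejected(self):
        spec = SpeciesTreeSpec(
            taxon_labels=("A", "B", "C"), topology="((A:1,B:2):1,C:2);"
        )
        with pytest.raises(TreeError, match="ultrametric"):
            build_species_tree(spec)

    def test_zero_internode_override_accepted_and_maximally_discordant(self):
        spec = SpeciesTreeSpec(
            taxon_labels=("A", "B", "C"),
            topology="((A:1,B:1):1,C:2);",
            internode_lengths={frozenset({"A", "B"}): 0.0},
        )
        tree = build_species_tree(spec)
        # at T=0 the three gene-tree topologies are equiprobable
        rng = np.random.default_rng(0)
        counts = {"AB": 0, "AC": 0, "BC": 0}
        n = 6000
        for _ in range(n):
            gt = sample_gene_tree(tree, rng=rng)
            pair = min(
                (frozenset(s) for s in clade_sets_3(gt)), key=len
            )
            counts["".join(sorted(pair))] += 1
        for v in counts.values():
            assert abs(v / n - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / n)

    def test_override_missing_branch_rejected(self):
        spec = SpeciesTreeSpec(
            taxon_labels=("A", "B", "C"),
            topology="((A:1,B:1):1,C:2);",
            internode_lengths={frozenset({"A", "C"}): 0.5},
        )
        with pytest.raises(TreeError):
            build_species_tree(spec)


def clade_sets_3(gene_tree):
    """The cherry of a 3-taxon gene tree (the first pair to coalesce)."""
    sides = []
    for c in gene_tree.root.children:
        names = set()
        stack = [c]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                names.add(n.name)
            stack.extend(n.children)
        sides.append(names)
    return [next(s for s in sides if len(s) == 2)]


class TestCoalescent:
    def test_single_taxon_tree_is_one_leaf(self):
        spec = SpeciesTreeSpec(taxon_labels=("A",), topology="A:1;")
        tree = build_species_tree(spec) if False else tree_from_newick("A:1;")
        gt = sample_gene_tree(tree, seed=0)
        assert gt.n_leaves() == 1 and gt.root.is_leaf

    def test_mean_pairwise_coalescence_time_is_one(self):
        st = tree_from_newick("(A:1e-4,B:1e-4);")
        rng = np.random.default_rng(3)
        times = [
            sample_gene_tree(st, rng=rng).root.children[0].length
            for _ in range(10_000)
        ]
        mean = np.mean(times)
        se = np.std(times) / math.sqrt(len(times))
        assert abs(mean - (1.0 + 1e-4)) < 3 * se

    @pytest.mark.parametrize("T", [0.1, 0.5, 2.0])
    def test_three_taxon_concordance_law(self, T):
        st = tree_from_newick(f"((A:1,B:1):{T},C:{1 + T});")
        rng = np.random.default_rng(7)
        n = 20_000
        match = 0
        for _ in range(n):
            gt = sample_gene_tree(st, rng=rng)
            if clade_sets_3(gt)[0] == {"A", "B"}:
                match += 1
        expected = 1 - (2 / 3) * math.exp(-T)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(match / n - expected) < 3 * se

    def test_long_internodes_give_concordant_gene_trees(self):
        st = tree_from_newick("(((A:1,B:1):6,C:7):6,D:13);")
        matches = sum(
            rs.same_unrooted_topology(sample_gene_tree(st, seed=s), st)
            for s in range(2000)
        )
        assert matches / 2000 >= 0.99

    def test_introgression_full_pulse_reroutes_recipient(self):
        # donor B's branch spans [0,1); with proportion 1 at t=0.2 the C
        # lineage enters it, so C can never coalesce below 0.2, and any
        # coalescence of C below the donor branch top pairs it with B.
        st = tree_from_newick("((A:1,B:1):5,C:6);")
        ev = IntrogressionEvent(
            donor_branch=frozenset({"B"}),
            recipient_branch=frozenset({"C"}),
            time=0.2,
            proportion=1.0,
        )
        rng = np.random.default_rng(11)
        seen_donor_pairing = 0
        for _ in range(300):
            gt = sample_gene_tree(st, event=ev, rng=rng)
            c_leaf = next(l for l in gt.leaves() if l.name == "C")
            assert c_leaf.length >= 0.2
            if c_leaf.length < 1.0:  # coalesced inside the donor branch
                sibs = {
                    l.name
                    for l in gt.leaves()
                    if l is not c_leaf and l.parent is c_leaf.parent
                }
                assert sibs == {"B"}
                seen_donor_pairing += 1
        assert seen_donor_pairing > 100  # the pulse is actually exercised

    def test_zero_proportion_is_a_no_op_distribution(self):
        st = tree_from_newick("((A:1,B:1):1,C:2);")
        ev = IntrogressionEvent(
            donor_branch=frozenset({"B"}),
            recipient_branch=frozenset({"C"}),
            time=0.5,
            proportion=0.0,
        )
        rng = np.random.default_rng(5)
        n = 4000
        match = sum(
            clade_sets_3(sample_gene_tree(st, event=ev, rng=rng))[0] == {"A", "B"}
            for _ in range(n)
        )
        expected = 1 - (2 / 3) * math.exp(-1.0)
        assert abs(match / n - expected) < 3 * math.sqrt(expected * (1 - expected) / n)

    def test_event_on_missing_branch_rejected(self):
        st = tree_from_newick("((A:1,B:1):1,C:2);")
        ev = IntrogressionEvent(
            donor_branch=frozenset({"Z"}),
            recipient_branch=frozenset({"C"}),
            time=0.5,
            proportion=1.0,
        )
        with pytest.raises(TreeError):
            sample_gene_tree(st, event=ev, seed=0)

    def test_event_outside_branch_span_rejected(self):
        st = tree_from_newick("((A:1,B:1):1,C:2);")
        ev = IntrogressionEvent(
            donor_branch=frozenset({"B"}),
            recipient_branch=frozenset({"C"}),
            time=1.5,  # B's pendant branch ends at 1
            proportion=1.0,
        )
        with pytest.raises(TreeError):
            sample_gene_tree(st, event=ev, seed=0)


class TestSequenceSimulation:
    def test_zero_length_branches_copy_sequences(self, jc):
        gt = tree_from_newick("(A:0,B:0);")
        aln = simulate_alignment(gt, jc, 200, seed=1)
        assert aln.rows[0] == aln.rows[1]

    def test_jc_divergence_law(self, jc):
        gt = tree_from_newick("(A:0.05,B:0.05);")
        n = 100_000
        aln = simulate_alignment(gt, jc, n, seed=5)
        mism = sum(a != b for a, b in zip(aln.rows[0], aln.rows[1])) / n
        expected = 0.75 * (1 - math.exp(-4 * 0.1 / 3))
        assert abs(mism - expected) < 3 * math.sqrt(expected * (1 - expected) / n)

    def test_nonpositive_length_rejected(self, jc):
        gt = tree_from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            simulate_alignment(gt, jc, 0, seed=1)

    def test_nuclear_calibration_band(self):
        """HKY+G on the default tree at the study's target: mean pairwise
        distance within [0.02, 0.06] averaged over 50 seeds."""
        from radsplit.seqchar import mean_pairwise_distance
        from radsplit.synth import DEFAULT_NUCLEAR_MODEL, divergence_to_subs_scale, _scale_tree

        st = build_species_tree(SpeciesTreeSpec())
        rate = divergence_to_subs_scale(
            DEFAULT_NUCLEAR_MODEL, 0.04, expected_pairwise_coal_distance(st)
        )
        dists = []
        for seed in range(50):
            gt = sample_gene_tree(st, seed=seed)
            aln = simulate_alignment(_scale_tree(gt, rate), DEFAULT_NUCLEAR_MODEL, 500, seed=seed)
            dists.append(mean_pairwise_distance(aln))
        assert 0.02 <= np.mean(dists) <= 0.06


class TestStudyBundle:
    def test_default_shape(self):
        cfg = SimulationConfig(seed=1)
        bundle = generate_study(cfg)
        nuclear = bundle.nuclear_loci()
        assert len(nuclear) == 44
        for locus in nuclear:
            assert 337 <= locus.alignment.n_cols <= 868
        mt = bundle.mt_loci()
        assert sum(l.alignment.n_cols for l in mt) == 16527
        # single non-recombining mt history
        mt_trees = {id(bundle.gene_trees[l.name]) for l in mt}
        assert len(mt_trees) == 1

    def test_no_nuclear_loci_config(self):
        bundle = generate_study(SimulationConfig(n_nuclear_loci=0, seed=2))
        assert bundle.nuclear_loci() == []
        assert len(bundle.mt_loci()) == 17

    def test_deterministic_bundle_serialization(self):
        cfg = SimulationConfig(
            n_nuclear_loci=3, introgression=default_introgression_event(), seed=9
        )
        b1, b2 = generate_study(cfg), generate_study(cfg)
        for l1, l2 in zip(b1.loci, b2.loci):
            assert l1.name == l2.name and l1.alignment.rows == l2.alignment.rows
        for name in b1.gene_trees:
            assert b1.gene_trees[name].to_newick() == b2.gene_trees[name].to_newick()
        assert b1.manifest == b2.manifest

    def test_different_seeds_differ(self):
        a = generate_study(SimulationConfig(n_nuclear_loci=2, seed=1))
        b = generate_study(SimulationConfig(n_nuclear_loci=2, seed=2))
        assert a.loci[0].alignment.rows != b.loci[0].alignment.rows

    def test_manifest_matches_loci(self):
        bundle = generate_study(SimulationConfig(n_nuclear_loci=4, seed=3))
        by_name = {m["locus"]: m for m in bundle.manifest}
        for locus in bundle.loci:
            assert by_name[locus.name]["length"] == locus.alignment.n_cols
            assert by_name[locus.name]["locus_class"] == locus.locus_class
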