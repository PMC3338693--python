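import itertools
import math

import numpy as np
import pytest

import radsplit as rs
from radsplit.likelihood import (
    DEFAULT_CANDIDATES,
    LikelihoodError,
    PruningEngine,
    canonical_newick,
    fit_model,
    log_likelihood,
    nni_neighbors,
    nni_search,
    optimize_branch_lengths,
    select_model_aic,
    sitewise_lnL,
)
from radsplit.models import STATES
from radsplit.seqio import AMBIGUITY
from radsplit.trees import tree_from_newick

from conftest import random_alignment, random_tree


def enumeration_lnl(tree, alignment, model):
    """Independent oracle: explicit summation over all internal-state
    assignments per site (feasible for <=5 taxa)."""
    rates, weights = model.category_rates()
    freqs = np.asarray(model.base_freqs)
    left, lam, right = model.eigen()

    def pmat(t, r):
        if r == 0:
            return np.eye(4)
        return (left * np.exp(lam * t * r)) @ right

    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for site in range(alignment.n_cols):
        tip_state = {
            lbl: [STATES.index(s) for s in AMBIGUITY[alignment.row(lbl)[site]]]
            for lbl in alignment.labels
        }
        site_lik = 0.0
        for r, w in zip(rates, weights):
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                state = {id(n): a for n, a in zip(internals, assign)}
                term = freqs[state[id(tree.root)]]
                ok = True
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    p = pmat(node.length, r)
                    if node.is_leaf:
                        term *= sum(p[state[id(node.parent)], x] for x in tip_state[node.name])
                    else:
                        term *= p[state[id(node.parent)], state[id(node)]]
                    if term == 0.0:
                        ok = False
                        break
                if ok:
                    s += term
            site_lik += w * s
        total += math.log(site_lik)
    return total


class TestPruning:
    def test_identical_sequences_tiny_branch_limit(self, jc):
        aln = rs.Alignment(("A", "B"), ("ACGT" * 25, "ACGT" * 25))
        tree = tree_from_newick("(A:1e-9,B:1e-9);")
        assert log_likelihood(tree, aln, jc) == pytest.approx(100 * math.log(0.25), abs=1e-4)

    def test_matches_enumeration_four_taxa(self, four_taxon_tree, four_taxon_alignment, gtr_ig):
        mine = log_likelihood(four_taxon_tree, four_taxon_alignment, gtr_ig)
        oracle = enumeration_lnl(four_taxon_tree, four_taxon_alignment, gtr_ig)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_matches_enumeration_five_taxa_random(self, gtr_ig):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, list("ABCDE"))
        aln = random_alignment(rng, 5, 8, missing=0.15)
        aln = rs.Alignment(tuple("ABCDE"), tuple(aln.rows))
        mine = log_likelihood(tree, aln, gtr_ig)
        oracle = enumeration_lnl(tree, aln, gtr_ig)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_rerooting_invariance(self, four_taxon_tree, four_taxon_alignment, gtr_ig):
        ref = log_likelihood(four_taxon_tree, four_taxon_alignment, gtr_ig)
        for leaf in four_taxon_tree.leaves():
            rerooted = four_taxon_tree.reroot_at_edge(leaf)
            assert log_likelihood(rerooted, four_taxon_alignment, gtr_ig) == pytest.approx(
                ref, abs=1e-8
            )

    def test_unknown_branch_length_rejected(self, jc):
        aln = rs.Alignment(("A", "B"), ("ACGT", "ACGT"))
        with pytest.raises(LikelihoodError):
            log_likelihood(tree_from_newick("(A:1,B);"), aln, jc)


class TestSitewise:
    def test_sums_to_total(self, four_taxon_tree, four_taxon_alignment, gtr_ig):
        sw = sitewise_lnL(four_taxon_tree, four_taxon_alignment, gtr_ig)
        total = log_likelihood(four_taxon_tree, four_taxon_alignment, gtr_ig)
        assert sw.sum() == pytest.approx(total, abs=1e-8)
        assert len(sw) == four_taxon_alignment.n_cols

    def test_identical_sites_approach_log_quarter(self, jc):
        aln = rs.Alignment(("A", "B"), ("AAAA", "AAAA"))
        tree = tree_from_newick("(A:1e-9,B:1e-9);")
        np.testing.assert_allclose(sitewise_lnL(tree, aln, jc), math.log(0.25), atol=1e-6)

    def test_matches_per_site_enumeration(self, gtr_ig):
        tree = tree_from_newick("((A:0.2,B:0.1):0.05,(C:0.15,D:0.3):0.1);")
        aln = rs.Alignment(("A", "B", "C", "D"), ("ACG", "ATG", "CCG", "ACT"))
        sw = sitewise_lnL(tree, aln, gtr_ig)
        for site in range(3):
            sub = aln.columns([site])
            assert sw[site] == pytest.approx(enumeration_lnl(tree, sub, gtr_ig), abs=1e-10)


class TestBranchOptimization:
    def test_recovers_simulated_length(self, jc):
        # t = 0.1 split across a two-taxon tree, 100 kb of JC sites
        truth = tree_from_newick("(A:0.05,B:0.05);")
        aln = rs.simulate_alignment(truth, jc, 100_000, seed=11)
        start = tree_from_newick("(A:0.02,B:0.02);")
        opt, _ = optimize_branch_lengths(start, aln, jc)
        total = sum(n.length for n in opt.postorder() if n.parent is not None)
        p_hat = 0.75 * (1 - math.exp(-4 * 0.1 / 3))
        se_t = 3 * math.sqrt(p_hat * (1 - p_hat) / 100_000) / (1 - 4 * p_hat / 3)
        assert abs(total - 0.1) < se_t

    def test_fixed_point_at_optimum(self, jc):
        truth = tree_from_newick("(A:0.05,B:0.05);")
        aln = rs.simulate_alignment(truth, jc, 5000, seed=3)
        opt, lnl1 = optimize_branch_lengths(truth, aln, jc)
        again, lnl2 = optimize_branch_lengths(opt, aln, jc)
        assert lnl2 >= lnl1 - 1e-9
        assert lnl2 - lnl1 < 1e-3

    def test_never_decreases_on_random_fixtures(self, jc):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = random_tree(rng, list("ABCDE"))
            aln = random_alignment(rng, 5, 60)
            aln = rs.Alignment(tuple("ABCDE"), tuple(aln.rows))
            start_lnl = log_likelihood(tree, aln, jc)
            _, end_lnl = optimize_branch_lengths(tree, aln, jc)
            assert end_lnl >= start_lnl - 1e-9


class TestNNISearch:
    def test_four_taxa_equals_exhaustive(self, jc):
        truth = tree_from_newick("((A:0.1,B:0.1):0.08,(C:0.1,D:0.1):0.08);")
        aln = rs.simulate_alignment(truth, jc, 1500, seed=13)
        topologies = [
            "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);",
            "((A:0.1,C:0.1):0.05,(B:0.1,D:0.1):0.05);",
            "((A:0.1,D:0.1):0.05,(B:0.1,C:0.1):0.05);",
        ]
        best_lnl, best_tree = -np.inf, None
        for nwk in topologies:
            opt, lnl = optimize_branch_lengths(tree_from_newick(nwk), aln, jc)
            if lnl > best_lnl:
                best_lnl, best_tree = lnl, opt
        found, found_lnl = nni_search(tree_from_newick(topologies[1]), aln, jc)
        assert rs.same_unrooted_topology(found, best_tree)
        assert found_lnl == pytest.approx(best_lnl, abs=1e-3)

    def test_recovers_truth_from_clean_simulation(self, jc):
        truth = tree_from_newick(
            "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,(E:0.1,F:0.1):0.1);"
        )
        aln = rs.simulate_alignment(truth, jc, 3000, seed=29)
        rng = np.random.default_rng(1)
        start = random_tree(rng, list("ABCDEF"))
        found, _ = nni_search(start, aln, jc)
        assert rs.same_unrooted_topology(found, truth)

    def test_lnl_never_below_start(self, jc):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, list("ABCDE"))
        aln = random_alignment(rng, 5, 80)
        aln = rs.Alignment(tuple("ABCDE"), tuple(aln.rows))
        start_opt, start_lnl = optimize_branch_lengths(tree, aln, jc)
        _, end_lnl = nni_search(tree, aln, jc)
        assert end_lnl >= start_lnl - 1e-6

    def test_neighbor_count(self):
        rng = np.random.default_rng(9)
        for n in (4, 6, 8):
            tree = random_tree(rng, [f"x{i}" for i in range(n)])
            assert len(nni_neighbors(tree)) == 2 * (n - 3)


class TestModelSelection:
    def test_aic_consistent_and_sorted(self, jc):
        truth = tree_from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln = rs.simulate_alignment(truth, jc, 800, seed=17)
        fits = select_model_aic(aln, truth, candidate_set=("JC69", "K80", "HKY85"))
        assert [f.aic for f in fits] == sorted(f.aic for f in fits)
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.lnL, abs=1e-6)

    def test_nested_models_lnl_ordering(self, jc):
        # a richer nested model can never fit worse at the optimum
        truth = tree_from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln = rs.simulate_alignment(truth, jc, 800, seed=18)
        jc_fit = fit_model(aln, truth, "JC69")
        k80_fit = fit_model(aln, truth, "K80")
        assert k80_fit.lnL >= jc_fit.lnL - 1e-3
        assert k80_fit.n_params == jc_fit.n_params + 1

    def test_gamma_data_prefers_gamma_model(self):
        model = rs.model_from_id("HKY85+G", base_freqs=(0.3, 0.2, 0.2, 0.3),
                                 kappa=4.0, alpha=0.3)
        truth = tree_from_newick(
            "((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15);"
        )
        aln = rs.simulate_alignment(truth, model, 4000, seed=23)
        fits = select_model_aic(aln, truth)
        with_g = min(f.aic for f in fits if "+G" in f.model_id)
        without_g = min(f.aic for f in fits if "G" not in f.model_id)
        assert with_g < without_g

    def test_empty_candidate_set_rejected(self, four_taxon_tree, four_taxon_alignment):
        with pytest.raises(ValueError):
            select_model_aic(four_taxon_alignment, four_taxon_tree, candidate_set=())
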