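import warnings

import numpy as np
import pytest

from sitepart.alignment import Alignment
from sitepart.likelihood import (
    LabelMismatchError,
    TreeLikelihood,
    fit_branch_scale,
    log_likelihood,
    optimize_branch_lengths,
)
from sitepart.simulate import simulate_alignment
from sitepart.substitution import ExchangeabilityMatrix, build_rate_matrix
from sitepart.trees import PhyloTree, random_tree

from conftest import random_model


class TestPruning:
    def test_two_taxon_closed_form(self):
        tree = PhyloTree.from_newick("(a:0.3,b:0.2);")
        R, pi = random_model(1)
        Q = build_rate_matrix(R, pi)
        msa = Alignment.from_sequences(["a", "b"], ["A", "R"])
        from sitepart.substitution import transition_matrix

        P = transition_matrix(Q, 0.5)
        assert log_likelihood(msa, tree, Q, pi=pi) == pytest.approx(
            np.log(pi[0] * P[0, 1]), abs=1e-10
        )

    @pytest.mark.parametrize("n_taxa", [3, 4, 5])
    def test_matches_brute_force_enumeration(self, brute_force, n_taxa):
        R, pi = random_model(n_taxa * 7)
        tree = random_tree(n_taxa, 0.25, seed=n_taxa)
        msa = simulate_alignment(tree, R, pi, 40, seed=n_taxa + 1)
        Q = build_rate_matrix(R, pi)
        ll = log_likelihood(msa, tree, Q, pi=pi)
        oracle = brute_force(msa, tree, Q.q, pi)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_missing_data_marginalised(self, brute_force):
        R, pi = random_model(5)
        tree = random_tree(4, 0.3, seed=9)
        msa = Alignment.from_sequences(tree.leaf_names, ["AR-X", "ARND", "A-ND", "ARN-"])
        Q = build_rate_matrix(R, pi)
        assert log_likelihood(msa, tree, Q, pi=pi) == pytest.approx(
            brute_force(msa, tree, Q.q, pi), abs=1e-8
        )

    def test_root_placement_invariance(self, small_instance):
        import dendropy

        msa, tree, R, pi = small_instance
        Q = build_rate_matrix(R, pi)
        ll = log_likelihood(msa, tree, Q, pi=pi)
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        for edge in list(dt.preorder_edge_iter())[3:5]:
            if edge.length is None:
                continue
            dt2 = dt.clone(depth=1)
            e2 = list(dt2.preorder_edge_iter())[list(dt.preorder_edge_iter()).index(edge)]
            dt2.reroot_at_edge(e2, length1=e2.length / 2, length2=e2.length / 2)
            rerooted = PhyloTree.from_dendropy(dt2)
            assert log_likelihood(msa, rerooted, Q, pi=pi) == pytest.approx(ll, abs=1e-8)

    def test_exchangeability_scale_invariance(self, small_instance):
        msa, tree, R, pi = small_instance
        ll1 = log_likelihood(msa, tree, build_rate_matrix(R, pi), pi=pi)
        ll2 = log_likelihood(msa, tree, build_rate_matrix(R.scaled(7.0), pi), pi=pi)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_label_mismatch_lists_names(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.1,c:0.1);")
        msa = Alignment.from_sequences(["a", "b", "zzz"], ["A", "A", "A"])
        with pytest.raises(LabelMismatchError, match="zzz"):
            TreeLikelihood(msa, tree)


class TestGradients:
    def test_analytic_matches_finite_differences(self, small_instance):
        msa, tree, R, pi = small_instance
        engine = TreeLikelihood(msa, tree, pi=pi)
        rng = np.random.default_rng(2)
        pairs = np.exp(rng.normal(0, 0.4, 190))
        t = tree.branch_lengths
        ll, g_pairs, g_t = engine.loglike_grad(pairs, t)
        eps = 1e-6
        for idx in [0, 17, 95, 189]:
            bumped = pairs.copy()
            bumped[idx] += eps
            num = (engine.loglike(bumped, t) - ll) / eps
            assert g_pairs[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            tb = t.copy()
            tb[v] += eps
            num = (engine.loglike(pairs, tb) - ll) / eps
            assert g_t[v] == pytest.approx(num, rel=1e-3, abs=1e-5)


class TestBranchLengths:
    def test_recovery_within_fifteen_percent(self):
        R, pi = random_model(31)
        tree = random_tree(6, 0.15, seed=32)
        msa = simulate_alignment(tree, R, pi, 5000, seed=33)
        Q = build_rate_matrix(R, pi)
        start = tree.with_branch_lengths(np.full(tree.n_nodes, 0.1))
        fitted = optimize_branch_lengths(msa, start, Q, pi=pi)
        truth = tree.branch_map()
        for key, est in fitted.branch_map().items():
            if truth[key] >= 0.05:
                assert abs(est - truth[key]) / truth[key] < 0.15

    def test_identical_sequences_drive_lengths_to_bound(self):
        R, pi = random_model(34)
        tree = random_tree(5, 0.2, seed=35)
        msa = Alignment.from_sequences(tree.leaf_names, ["ACDEF"] * 5)
        fitted = optimize_branch_lengths(msa, tree, build_rate_matrix(R, pi), pi=pi)
        assert fitted.total_length < 1e-5

    def test_start_at_optimum_changes_little(self):
        R, pi = random_model(36)
        tree = random_tree(5, 0.2, seed=37)
        msa = simulate_alignment(tree, R, pi, 800, seed=38)
        Q = build_rate_matrix(R, pi)
        first = optimize_branch_lengths(msa, tree, Q, pi=pi)
        ll_first = log_likelihood(msa, first, Q, pi=pi)
        again = optimize_branch_lengths(msa, first, Q, pi=pi)
        assert log_likelihood(msa, again, Q, pi=pi) == pytest.approx(ll_first, abs=0.01)

    def test_loglik_never_decreases_from_start(self):
        R, pi = random_model(39)
        tree = random_tree(5, 0.2, seed=40)
        msa = simulate_alignment(tree, R, pi, 300, seed=41)
        Q = build_rate_matrix(R, pi)
        start = tree.with_branch_lengths(np.full(tree.n_nodes, 0.5))
        fitted = optimize_branch_lengths(msa, start, Q, pi=pi)
        assert log_likelihood(msa, fitted, Q, pi=pi) >= log_likelihood(msa, start, Q, pi=pi)


class TestBranchScale:
    def test_self_consistency_scale_one(self):
        R, pi = random_model(42)
        tree = random_tree(6, 0.2, seed=43)
        msa = simulate_alignment(tree, R, pi, 2000, seed=44)
        Q = build_rate_matrix(R, pi)
        fitted = optimize_branch_lengths(msa, tree, Q, pi=pi)
        s, _ = fit_branch_scale(msa, fitted, Q, pi=pi)
        assert s == pytest.approx(1.0, abs=1e-3)

    def test_doubled_tree_recovers_two(self):
        R, pi = random_model(45)
        tree = random_tree(6, 0.15, seed=46)
        msa = simulate_alignment(tree.rescaled(2.0), R, pi, 3000, seed=47)
        s, _ = fit_branch_scale(msa, tree, build_rate_matrix(R, pi), pi=pi)
        assert s == pytest.approx(2.0, rel=0.10)

    def test_boundary_solution_warns(self):
        R, pi = random_model(48)
        tree = random_tree(4, 0.2, seed=49)
        msa = Alignment.from_sequences(tree.leaf_names, ["ACDE"] * 4)
        with pytest.warns(RuntimeWarning, match="boundary"):
            fit_branch_scale(msa, tree, build_rate_matrix(R, pi), pi=pi)

    def test_disjoint_taxa_rejected(self):
        R, pi = random_model(50)
        tree = random_tree(4, 0.2, seed=51)
        msa = Alignment.from_sequences(["p", "q", "r", "s"], ["A", "A", "A", "A"])
        with pytest.raises(LabelMismatchError):
            fit_branch_scale(msa, tree, build_rate_matrix(R, pi), pi=pi)
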