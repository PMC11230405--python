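"""Trees, substitution models, and pruning likelihoods."""

import numpy as np
import pytest

import convreg as cv
from convreg.phylo import MISSING

from conftest import brute_force_column_loglik


# -- Newick parsing -------------------------------------------------------

class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self, tree):
        again = cv.PhyloTree.from_newick(tree.to_newick())
        assert sorted(again.leaf_names) == sorted(tree.leaf_names)
        assert again.to_newick() == tree.to_newick()
        np.testing.assert_allclose(sorted(again.lengths),
                                   sorted(tree.lengths))

    def test_missing_branch_lengths_default_to_zero(self):
        t = cv.PhyloTree.from_newick("(a,b,(c,d));")
        assert t.total_length() == 0.0
        assert sorted(t.leaf_names) == ["a", "b", "c", "d"]

    @pytest.mark.parametrize("bad", [
        "((a:1,b:1):1;",            # unbalanced parens
        "(a:1,a:1);",               # duplicate leaf names
        "(a:-0.5,b:1);",            # negative branch length
        "(a:1,b:1)",                # missing semicolon
    ])
    def test_malformed_newick_raises(self, bad):
        with pytest.raises(cv.NewickError):
            cv.PhyloTree.from_newick(bad)

    def test_branch_index_finds_leaves_and_rejects_unknown(self, tree):
        i = tree.branch_index("hib_A")
        assert tree.labels[i] == "hib_A"
        with pytest.raises(KeyError):
            tree.branch_index("nonexistent_species")


# -- substitution model ---------------------------------------------------

class TestSubstitutionModel:
    def test_zero_time_transition_is_identity(self, jc, hky):
        for model in (jc, hky):
            np.testing.assert_allclose(model.transition_matrix(0.0),
                                       np.eye(4), atol=1e-12)

    def test_rows_are_probability_distributions(self, hky, rng):
        for t in rng.uniform(0.01, 5.0, size=20):
            P = hky.transition_matrix(t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)

    def test_long_time_limit_is_equilibrium(self, hky):
        P = hky.transition_matrix(500.0)
        np.testing.assert_allclose(P, np.tile(hky.pi, (4, 1)), atol=1e-8)

    def test_chapman_kolmogorov(self, hky):
        # P(s+t) = P(s) P(t)
        np.testing.assert_allclose(
            hky.transition_matrix(0.7),
            hky.transition_matrix(0.3) @ hky.transition_matrix(0.4),
            atol=1e-12)

    def test_jukes_cantor_closed_form(self, jc):
        # P_same(t) = 1/4 + 3/4 exp(-4t/3)
        t = 0.1
        P = jc.transition_matrix(t)
        same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = np.full((4, 4), diff)
        np.fill_diagonal(expected, same)
        np.testing.assert_allclose(P, expected, atol=1e-12)
        assert abs(P[0, 0] - 0.9063799892822106) < 1e-12

    def test_detailed_balance_reversibility(self, hky):
        P = hky.transition_matrix(0.5)
        flow = hky.pi[:, None] * P
        np.testing.assert_allclose(flow, flow.T, atol=1e-12)

    def test_unit_branch_length_is_one_expected_substitution(self, hky):
        assert abs(-(hky.pi @ np.diag(hky.Q)) - 1.0) < 1e-12

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            cv.HKYModel(pi=[0.5, 0.5, 0.2, -0.2])
        with pytest.raises(ValueError):
            cv.HKYModel(kappa=0.0)
        with pytest.raises(ValueError):
            cv.HKYModel().transition_matrix(-0.1)


# -- pruning likelihoods --------------------------------------------------

class TestPruningLikelihood:
    def test_single_leaf_equilibrium_probability(self, jc):
        t = cv.PhyloTree.from_newick("(a:0.1,b:0.2);")
        ll = cv.column_log_likelihood(t, jc, {"a": "A", "b": "-"})
        assert abs(ll - np.log(0.25)) < 1e-12

    def test_all_missing_column_has_likelihood_one(self, tree, jc):
        col = {name: "-" for name in tree.leaf_names}
        assert abs(cv.column_log_likelihood(tree, jc, col)) < 1e-12

    def test_two_leaf_matching_column_closed_form(self, jc):
        # L = sum_x pi_x P_xA(t1) P_xA(t2); for JC with t1=t2=0.1 this is
        # 0.25 * (Psame^2 + 3 Pdiff^2) = 0.206112...
        t = cv.PhyloTree.from_newick("(a:0.1,b:0.1);")
        ll = cv.column_log_likelihood(t, jc, {"a": "A", "b": "A"})
        psame = 0.25 + 0.75 * np.exp(-0.4 / 3)
        pdiff = 0.25 - 0.25 * np.exp(-0.4 / 3)
        expected = 0.25 * (psame ** 2 + 3 * pdiff ** 2)
        assert abs(ll - np.log(expected)) < 1e-12

    def test_matches_brute_force_enumeration_small_trees(self, jc, hky, rng):
        newicks = [
            "(a:0.1,b:0.3);",
            "((a:0.2,b:0.1):0.15,c:0.3);",
            "(((a:0.1,b:0.2):0.1,c:0.3):0.05,(d:0.25,e:0.15):0.1);",
        ]
        for nwk in newicks:
            t = cv.PhyloTree.from_newick(nwk)
            for model in (jc, hky):
                tl = cv.TreeLikelihood(t, model)
                cols = rng.integers(0, 5, size=(t.n_leaves, 20)).astype(np.int8)
                got = tl.column_log_likelihoods(cols)
                for j in range(cols.shape[1]):
                    want = brute_force_column_loglik(t, model, cols[:, j])
                    assert abs(got[j] - want) <= 1e-10 * max(1.0, abs(want))

    def test_branch_scale_matches_brute_force(self, hky, rng):
        t = cv.PhyloTree.from_newick("((a:0.2,b:0.1):0.15,c:0.3);")
        tl = cv.TreeLikelihood(t, hky)
        cols = rng.integers(0, 4, size=(3, 10)).astype(np.int8)
        got = tl.column_log_likelihoods(cols, scale=0.3,
                                        branch_scales={"a": 5.0})
        for j in range(cols.shape[1]):
            want = brute_force_column_loglik(t, hky, cols[:, j], scale=0.3,
                                             branch_scales={"a": 5.0})
            np.testing.assert_allclose(got[j], want, rtol=1e-10)

    def test_likelihood_invariant_to_child_order(self, jc, rng):
        t1 = cv.PhyloTree.from_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        t2 = cv.PhyloTree.from_newick("(c:0.3,(b:0.2,a:0.1):0.1);")
        cols = rng.integers(0, 4, size=(3, 50)).astype(np.int8)
        order2 = [t1.leaf_names.index(n) for n in t2.leaf_names]
        l1 = cv.TreeLikelihood(t1, jc).column_log_likelihoods(cols)
        l2 = cv.TreeLikelihood(t2, jc).column_log_likelihoods(cols[order2])
        np.testing.assert_allclose(l1, l2, rtol=1e-12)

    def test_root_placement_invariance_under_reversibility(self, hky, rng):
        # the same unrooted tree rooted on two different edges
        t1 = cv.PhyloTree.from_newick("((a:0.1,b:0.2):0.06,(c:0.3,d:0.25):0.09);")
        t2 = cv.PhyloTree.from_newick("(((c:0.3,d:0.25):0.15,b:0.2):0.1,a:0.0);")
        cols = rng.integers(0, 5, size=(4, 40)).astype(np.int8)
        order2 = [t1.leaf_names.index(n) for n in t2.leaf_names]
        l1 = cv.TreeLikelihood(t1, hky).column_log_likelihoods(cols)
        l2 = cv.TreeLikelihood(t2, hky).column_log_likelihoods(cols[order2])
        np.testing.assert_allclose(l1, l2, rtol=1e-10)

    def test_scale_and_lengths_enter_only_as_product(self, tree, jc, rng):
        cols = rng.integers(0, 4, size=(tree.n_leaves, 30)).astype(np.int8)
        tl = cv.TreeLikelihood(tree, jc)
        half = cv.PhyloTree(tree.parent, tree.lengths * 0.5, tree.labels,
                            tree.is_leaf)
        l1 = tl.column_log_likelihoods(cols, scale=0.5)
        l2 = cv.TreeLikelihood(half, jc).column_log_likelihoods(cols)
        np.testing.assert_allclose(l1, l2, rtol=1e-12)

    def test_no_underflow_on_many_leaves(self, jc):
        # 64-leaf caterpillar: naive products of 1e-1-scale terms underflow
        inner = "a0:0.1"
        for i in range(1, 64):
            inner = f"({inner},a{i}:0.1):0.05"
        big = cv.PhyloTree.from_newick(inner + ";")
        cols = np.tile(np.arange(4, dtype=np.int8), (big.n_leaves, 25))[:, :25]
        ll = cv.TreeLikelihood(big, jc).column_log_likelihoods(cols)
        assert np.all(np.isfinite(ll))

    def test_mismatched_column_raises(self, tree, jc):
        with pytest.raises(ValueError):
            cv.column_log_likelihood(tree, jc, {"hib_A": "A"})
        with pytest.raises(ValueError):
            cv.TreeLikelihood(tree, jc).column_log_likelihoods(
                np.zeros((3, 5), dtype=np.int8))


# -- simulation -----------------------------------------------------------

class TestSimulateColumns:
    def test_deterministic_for_fixed_seed(self, tree, jc):
        a = cv.simulate_columns(tree, jc, 100, rng=7)
        b = cv.simulate_columns(tree, jc, 100, rng=7)
        np.testing.assert_array_equal(a, b)

    def test_zero_branch_lengths_copy_root_state(self, jc):
        t = cv.PhyloTree.from_newick("(a:0,b:0,c:0);")
        cols = cv.simulate_columns(t, jc, 200, rng=3)
        assert np.all(cols == cols[0])

    def test_column_frequencies_match_analytic_distribution(self, jc):
        # 2-leaf JC tree: P(match) = sum_x pi_x Psame(t1) Psame(t2) + ...
        t = cv.PhyloTree.from_newick("(a:0.2,b:0.3);")
        n = 40000
        cols = cv.simulate_columns(t, jc, n, rng=11)
        psame = lambda tt: 0.25 + 0.75 * np.exp(-4 * tt / 3)
        p_match = 0.25 * (4 * (psame(0.2) * psame(0.3)
                               + 3 * ((1 - psame(0.2)) / 3)
                               * ((1 - psame(0.3)) / 3)))
        observed = float((cols[0] == cols[1]).mean())
        # binomial 4-sigma band
        sd = np.sqrt(p_match * (1 - p_match) / n)
        assert abs(observed - p_match) < 4 * sd

    def test_branch_scale_accelerates_one_lineage(self, tree, jc):
        cols_slow = cv.simulate_columns(tree, jc, 4000, scale=0.3, rng=5)
        cols_fast = cv.simulate_columns(tree, jc, 4000, scale=0.3,
                                        branch_scales={"hib_A": 8.0}, rng=5)
        i_hib = tree.leaf_names.index("hib_A")
        i_ctrl = tree.leaf_names.index("ctrl_A")
        mismatch_slow = (cols_slow[i_hib] != cols_slow[i_ctrl]).mean()
        mismatch_fast = (cols_fast[i_hib] != cols_fast[i_ctrl]).mean()
        assert mismatch_fast > mismatch_slow + 0.05
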