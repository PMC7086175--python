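import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from orgflux.ancestral import (
    AceError,
    MkModel,
    fit_mk,
    lrt_er_vs_ard,
    marginal_probabilities,
    transition_matrix,
    tree_log_likelihood,
)
from orgflux.simulate import simulate_species_tree, simulate_trait
from orgflux.trees import read_newick
from oracle_utils import enumeration_log_likelihood, enumeration_marginals


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        P = transition_matrix(MkModel(0.3, 0.7), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_symmetric_long_time_limit(self):
        P = transition_matrix(MkModel(1.0, 1.0), 1e6)
        assert np.allclose(P, 0.5)

    @pytest.mark.parametrize(
        "alpha,beta,t",
        [(0.2, 0.6, 1.0), (1.5, 0.1, 0.3), (0.01, 0.01, 10.0), (3.0, 2.0, 0.05)],
    )
    def test_matches_matrix_exponential(self, alpha, beta, t):
        Q = np.array([[-alpha, alpha], [beta, -beta]])
        assert np.allclose(
            transition_matrix(MkModel(alpha, beta), t), expm(Q * t), atol=1e-10
        )

    def test_rows_stochastic(self):
        P = transition_matrix(MkModel(0.37, 1.21), 2.5)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= 0).all() and (P <= 1).all()

    def test_negative_time_rejected(self):
        with pytest.raises(AceError):
            transition_matrix(MkModel(1, 1), -0.1)


class TestLogLikelihood:
    def test_cherry_matches_enumeration(self):
        tree = read_newick("(A:1,B:1);")
        tips = {"A": 0, "B": 1}
        model = MkModel(1.0, 1.0)
        assert math.isclose(
            tree_log_likelihood(tree, tips, model),
            enumeration_log_likelihood(tree, tips, model),
            abs_tol=1e-10,
        )

    def test_no_event_limit_reaches_root_prior(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        tips = {"A": 0, "B": 0, "C": 0}
        logL = tree_log_likelihood(tree, tips, MkModel(1e-8, 1e-8))
        assert math.isclose(logL, math.log(0.5), abs_tol=1e-6)

    def test_state_flip_and_rate_swap_symmetry(self):
        tree = read_newick("((A:0.6,B:1.2):0.4,(C:0.8,D:0.2):1.1);")
        tips = {"A": 0, "B": 1, "C": 1, "D": 0}
        flipped = {k: 1 - v for k, v in tips.items()}
        m = MkModel(0.3, 0.9)
        m_swapped = MkModel(0.9, 0.3)
        assert math.isclose(
            tree_log_likelihood(tree, tips, m),
            tree_log_likelihood(tree, flipped, m_swapped),
            abs_tol=1e-10,
        )

    def test_leaf_order_invariance(self):
        t1 = read_newick("((A:1,B:2):0.5,C:0.7);")
        t2 = read_newick("(C:0.7,(B:2,A:1):0.5);")
        tips = {"A": 1, "B": 0, "C": 1}
        m = MkModel(0.4, 0.2)
        assert math.isclose(
            tree_log_likelihood(t1, tips, m),
            tree_log_likelihood(t2, tips, m),
            abs_tol=1e-12,
        )

    def test_random_trees_match_enumeration(self, rng):
        for _ in range(60):
            tree, _ = simulate_species_tree(int(rng.integers(3, 7)), 1.0, rng)
            tips = {lb: int(rng.integers(2)) for lb in tree.leaf_labels}
            model = MkModel(float(rng.uniform(0.02, 2)), float(rng.uniform(0.02, 2)))
            assert math.isclose(
                tree_log_likelihood(tree, tips, model),
                enumeration_log_likelihood(tree, tips, model),
                abs_tol=1e-8,
            )

    def test_missing_tip_state_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(AceError, match="B"):
            tree_log_likelihood(tree, {"A": 0}, MkModel(1, 1))

    def test_missing_branch_length_rejected(self):
        tree = read_newick("(A:1,B);")
        with pytest.raises(AceError, match="length"):
            tree_log_likelihood(tree, {"A": 0, "B": 1}, MkModel(1, 1))


class TestMarginals:
    def test_symmetric_cherry_root_is_half(self):
        tree = read_newick("(A:1,B:1);")
        marg = marginal_probabilities(tree, {"A": 0, "B": 1}, MkModel(1.0, 1.0))
        assert math.isclose(marg[tree.root.index], 0.5, abs_tol=1e-12)

    def test_leaves_keep_observed_states(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        tips = {"A": 0, "B": 1, "C": 1}
        marg = marginal_probabilities(tree, tips, MkModel(0.5, 0.2))
        for lf in tree.leaves:
            assert math.isclose(marg[lf.index], tips[lf.label], abs_tol=1e-12)

    def test_four_tip_tree_matches_enumeration(self):
        tree = read_newick("((A:0.5,B:1.5):0.5,(C:0.3,D:0.9):0.8);")
        tips = {"A": 1, "B": 0, "C": 1, "D": 1}
        model = MkModel(0.25, 0.75)
        expected = enumeration_marginals(tree, tips, model)
        got = marginal_probabilities(tree, tips, model)
        for i in expected:
            assert math.isclose(got[i], expected[i], abs_tol=1e-8)

    def test_random_trees_match_enumeration(self, rng):
        for _ in range(40):
            tree, _ = simulate_species_tree(int(rng.integers(3, 7)), 1.0, rng)
            tips = {lb: int(rng.integers(2)) for lb in tree.leaf_labels}
            model = MkModel(float(rng.uniform(0.05, 2)), float(rng.uniform(0.05, 2)))
            expected = enumeration_marginals(tree, tips, model)
            got = marginal_probabilities(tree, tips, model)
            for i in expected:
                assert math.isclose(got[i], expected[i], abs_tol=1e-8)

    def test_branch_rescaling_invariance(self):
        tree1 = read_newick("((A:0.5,B:1.5):0.5,(C:0.3,D:0.9):0.8);")
        tree2 = read_newick("((A:5,B:15):5,(C:3,D:9):8);")
        tips = {"A": 1, "B": 0, "C": 1, "D": 1}
        m1 = marginal_probabilities(tree1, tips, MkModel(0.5, 0.3))
        m2 = marginal_probabilities(tree2, tips, MkModel(0.05, 0.03))
        for i in m1:
            assert math.isclose(m1[i], m2[i], abs_tol=1e-10)


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, rng):
        from orgflux.ancestral import _Pruner

        for _ in range(20):
            tree, _ = simulate_species_tree(int(rng.integers(4, 20)), 1.0, rng)
            tips = {lb: int(rng.integers(2)) for lb in tree.leaf_labels}
            pruner = _Pruner(tree, tips)
            a = float(rng.uniform(0.05, 2))
            b = float(rng.uniform(0.05, 2))
            _, ga, gb = pruner.log_likelihood_grad(MkModel(a, b))
            h = 1e-6
            na = (
                pruner.log_likelihood(MkModel(a + h, b))
                - pruner.log_likelihood(MkModel(a - h, b))
            ) / (2 * h)
            nb = (
                pruner.log_likelihood(MkModel(a, b + h))
                - pruner.log_likelihood(MkModel(a, b - h))
            ) / (2 * h)
            assert math.isclose(ga, na, rel_tol=1e-4, abs_tol=1e-4)
            assert math.isclose(gb, nb, rel_tol=1e-4, abs_tol=1e-4)


class TestFit:
    def test_monomorphic_tips_hit_boundary(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        fit = fit_mk(tree, {"A": 1, "B": 1, "C": 1}, "ARD")
        assert fit.at_boundary

    def test_ard_never_below_er(self, rng):
        for _ in range(10):
            tree, _ = simulate_species_tree(int(rng.integers(4, 8)), 1.0, rng)
            tips = {lb: int(rng.integers(2)) for lb in tree.leaf_labels}
            fit_er = fit_mk(tree, tips, "ER")
            fit_ard = fit_mk(tree, tips, "ARD")
            assert fit_ard.log_likelihood >= fit_er.log_likelihood - 1e-6

    def test_deterministic(self):
        tree = read_newick("((A:1,B:0.4):1,(C:2,D:0.2):0.3);")
        tips = {"A": 0, "B": 1, "C": 1, "D": 0}
        f1 = fit_mk(tree, tips, "ARD")
        f2 = fit_mk(tree, tips, "ARD")
        assert f1.model == f2.model
        assert f1.log_likelihood == f2.log_likelihood

    def test_parameter_recovery_order_of_magnitude(self, rng):
        # small-replicate smoke check; the acceptance suite runs the full
        # 50-replicate median-recovery version
        alphas, betas = [], []
        for _ in range(10):
            tree, _ = simulate_species_tree(200, 1.0, rng)
            tips, _, _ = simulate_trait(tree, set(), 0.1, 0.4, seed=rng)
            fit = fit_mk(tree, tips, "ARD", compute_marginals=False)
            alphas.append(fit.model.alpha)
            betas.append(fit.model.beta)
        assert 0.1 / 3 < np.median(alphas) < 0.1 * 3
        assert 0.4 / 3 < np.median(betas) < 0.4 * 3


class TestLrt:
    def test_equal_likelihoods_give_p_one(self):
        tree = read_newick("(A:1,B:1);")
        f = fit_mk(tree, {"A": 0, "B": 1}, "ER")
        stat, p = lrt_er_vs_ard(f, f)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        assert math.isclose(chi2.sf(3.841, 1), 0.05, abs_tol=5e-4)

    def test_worse_ard_raises(self):
        tree = read_newick("(A:1,B:1);")
        f1 = fit_mk(tree, {"A": 0, "B": 1}, "ER")
        f2 = fit_mk(tree, {"A": 0, "B": 1}, "ER")
        f2.log_likelihood -= 1.0
        with pytest.raises(AceError):
            lrt_er_vs_ard(f1, f2)
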