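import warnings

import numpy as np
import pytest
import scipy.linalg

import chromlik as ck
from chromlik.likelihood import ZeroLikelihoodWarning


def bichrom_theta(**overrides):
    base = dict(lambda0=0.01, lambda1=0.005, mu0=0.01, mu1=0.005,
                rho0=0.01, rho1=0.002, q01=0.01, q10=0.005,
                eps0=1e-6, eps1=1e-6)
    base.update(overrides)
    return np.log([base[k] for k in ck.BiChroMParams.names()])


class TestTransitionProbabilities:
    def test_zero_time_gives_identity(self, solanum_space):
        Q = ck.build_q_solanum(
            ck.SolanumParams(0.1, 0.01, 0.05, 0.02, 0.3, 0.4))
        assert np.array_equal(ck.transition_probabilities(Q, 0.0), np.eye(10))

    def test_rows_are_stochastic(self, bichrom_space, s1_params):
        Q = ck.build_q_bichrom(s1_params, bichrom_space)
        P = ck.transition_probabilities(Q, 0.37)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0 and P.max() <= 1.0

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_two_state_chain_matches_closed_form(self, t):
        """For rates a, b: P00(t) = (b + a e^{-(a+b)t}) / (a + b)."""
        a, b = 0.3, 0.7
        Q = np.array([[-a, a], [b, -b]])
        P = ck.transition_probabilities(Q, t)
        expected = (b + a * np.exp(-(a + b) * t)) / (a + b)
        assert P[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ck.InvalidArgumentError):
            ck.transition_probabilities(np.zeros((2, 2)), -0.5)


class TestRootPrior:
    def test_uniform_default(self):
        p = ck.RootPrior.uniform().probabilities(np.zeros((4, 4)), 4)
        assert np.allclose(p, 0.25)

    def test_stationary_satisfies_balance(self):
        a, b = 0.3, 0.7
        Q = np.array([[-a, a], [b, -b]])
        pi = ck.stationary_distribution(Q)
        assert np.allclose(pi, [b / (a + b), a / (a + b)])
        assert np.allclose(pi @ Q, 0.0, atol=1e-12)

    def test_custom_must_be_normalized(self):
        with pytest.raises(ck.InvalidArgumentError):
            ck.RootPrior.custom([0.5, 0.6])


class TestNegLogLik:
    def test_two_tip_tree_matches_direct_summation(self, bichrom_space):
        """-log sum_r pi_r P_{r,x}(t1) P_{r,y}(t2), dense exponentials."""
        tree = ck.read_newick("(A:1.3,B:0.6);")
        data = ck.TipObservations({"A": (4, 0), "B": (9, 1)})
        theta = bichrom_theta()
        model = ck.MODELS["bichrom"]
        got = ck.negloglik(tree, data, model.build, theta, bichrom_space)

        Qd = model.build(np.exp(theta), bichrom_space).dense()
        P1 = scipy.linalg.expm(Qd * 1.3)
        P2 = scipy.linalg.expm(Qd * 0.6)
        x = bichrom_space.index_of(4, 0)
        y = bichrom_space.index_of(9, 1)
        direct = -np.log(np.mean(P1[:, x] * P2[:, y]))
        assert got.value == pytest.approx(direct, rel=1e-10)

    def test_small_tree_matches_enumeration_oracle(
            self, oracle, small_space, four_tip_tree):
        data = ck.TipObservations({"A": (2, 0), "B": (5, 1),
                                   "C": (7, 0), "D": (1, 1)})
        theta = bichrom_theta(rho0=0.08, q01=0.2)
        model = ck.MODELS["bichrom"]
        got = ck.negloglik(four_tip_tree, data, model.build, theta,
                           small_space).value
        vectors = {lbl: ck.observation_to_vector(data[lbl], small_space)
                   for lbl in data}
        Qd = model.build(np.exp(theta), small_space).dense()
        prior = np.full(small_space.n_states, 1 / small_space.n_states)
        expected = oracle(four_tip_tree, vectors, Qd, prior)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_branches_same_state_gives_log_n(self, solanum_space):
        tree = ck.read_newick("(A:0.0,B:0.0);")
        data = ck.TipObservations({"A": (12, "H"), "B": (12, "H")})
        theta = np.log([0.1, 0.01, 0.05, 0.02, 0.3, 0.4])
        got = ck.negloglik(tree, data, ck.MODELS["solanum"].build, theta,
                           solanum_space)
        assert got.value == pytest.approx(np.log(10))
        assert got.expm_calls == 0

    def test_full_at_shared_rho_equals_reduced_exactly(
            self, bichrom_space, four_tip_tree, four_tip_obs):
        theta_full = bichrom_theta(rho0=0.004, rho1=0.004)
        theta_red = np.log([0.01, 0.005, 0.01, 0.005, 0.004,
                            0.01, 0.005, 1e-6, 1e-6])
        a = ck.negloglik(four_tip_tree, four_tip_obs,
                         ck.MODELS["bichrom"].build, theta_full,
                         bichrom_space).value
        b = ck.negloglik(four_tip_tree, four_tip_obs,
                         ck.MODELS["bichrom_reduced"].build, theta_red,
                         bichrom_space).value
        assert a == b

    def test_invariant_to_child_order(self, bichrom_space, four_tip_obs):
        theta = bichrom_theta()
        t1 = ck.read_newick("((A:3.1,B:0.4):1.2,(C:2.0,D:0.7):2.5);")
        t2 = ck.read_newick("((D:0.7,C:2.0):2.5,(B:0.4,A:3.1):1.2);")
        model = ck.MODELS["bichrom"]
        a = ck.negloglik(t1, four_tip_obs, model.build, theta, bichrom_space)
        b = ck.negloglik(t2, four_tip_obs, model.build, theta, bichrom_space)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_ambiguity_never_decreases_likelihood(
            self, bichrom_space, four_tip_tree, four_tip_obs):
        theta = bichrom_theta()
        model = ck.MODELS["bichrom"]
        sharp = ck.negloglik(four_tip_tree, four_tip_obs, model.build,
                             theta, bichrom_space).value
        relaxed_obs = ck.TipObservations(
            {**four_tip_obs.observations, "B": (None, None)})
        relaxed = ck.negloglik(four_tip_tree, relaxed_obs, model.build,
                               theta, bichrom_space).value
        assert relaxed <= sharp + 1e-12

    def test_taxon_mismatch_raises_data_error(
            self, bichrom_space, four_tip_tree):
        data = ck.TipObservations({"A": (5, 0), "B": (12, 1), "C": (26, 0),
                                   "X": (3, 1)})
        with pytest.raises(ck.DataError, match="differ"):
            ck.negloglik(four_tip_tree, data, ck.MODELS["bichrom"].build,
                         bichrom_theta(), bichrom_space)

    def test_fast_method_agrees_with_reference(
            self, bichrom_space, s1_params):
        Q = ck.build_q_bichrom(s1_params, bichrom_space)
        tree = ck.rescale_height(ck.simulate_yule_tree(60, 3), 50.0)
        tips = ck.simulate_tips(tree, Q, bichrom_space, seed=4)
        theta = bichrom_theta()
        model = ck.MODELS["bichrom"]
        ref = ck.negloglik(tree, tips, model.build, theta, bichrom_space)
        fast = ck.negloglik(tree, tips, model.build, theta, bichrom_space,
                            method="fast")
        assert fast.value == pytest.approx(ref.value, abs=1e-8)

    def test_expm_cached_per_unique_branch_length(self, bichrom_space):
        tree = ck.read_newick("((A:1.0,B:1.0):0.5,C:1.5);")
        data = ck.TipObservations({"A": (5, 0), "B": (6, 0), "C": (7, 1)})
        got = ck.negloglik(tree, data, ck.MODELS["bichrom"].build,
                           bichrom_theta(), bichrom_space)
        # lengths {1.0, 0.5, 1.5}: two 1.0-branches share one exponential
        assert got.expm_calls == 3
        assert got.cache_hits == 1

    def test_scaling_rescues_large_tree_underflow(
            self, bichrom_space, s1_params):
        Q = ck.build_q_bichrom(s1_params, bichrom_space)
        tree = ck.rescale_height(ck.simulate_yule_tree(1000, 5), 50.0)
        tips = ck.simulate_tips(tree, Q, bichrom_space, seed=6)
        # evaluate at rates far below the generating ones: the likelihood
        # of the many simulated changes drops below double-precision range
        theta = bichrom_theta(lambda0=1e-4, lambda1=1e-4, mu0=1e-4,
                              mu1=1e-4, rho0=1e-4, rho1=1e-4)
        model = ck.MODELS["bichrom"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroLikelihoodWarning)
            raw = ck.negloglik(tree, tips, model.build, theta, bichrom_space,
                               method="fast", scale=False)
        scaled = ck.negloglik(tree, tips, model.build, theta, bichrom_space,
                              method="fast")
        assert np.isinf(raw.value)
        assert np.isfinite(scaled.value)

    def test_scaled_and_unscaled_agree_on_mid_size_tree(
            self, bichrom_space, s1_params):
        Q = ck.build_q_bichrom(s1_params, bichrom_space)
        tree = ck.rescale_height(ck.simulate_yule_tree(50, 9), 50.0)
        tips = ck.simulate_tips(tree, Q, bichrom_space, seed=10)
        theta = bichrom_theta()
        model = ck.MODELS["bichrom"]
        a = ck.negloglik(tree, tips, model.build, theta, bichrom_space,
                         scale=False).value
        b = ck.negloglik(tree, tips, model.build, theta, bichrom_space).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_impossible_data_returns_inf_with_warning(self, solanum_space):
        # doubling-only model cannot reach 18 from 48
        tree = ck.read_newick("(A:0.0,B:0.0);")
        data = ck.TipObservations({"A": (48, "H"), "B": (18, "H")})
        theta = np.log([0.1, 0.1, 1e-300, 1e-300, 1e-300, 1e-300])
        with pytest.warns(ZeroLikelihoodWarning):
            got = ck.negloglik(tree, data, ck.MODELS["solanum"].build, theta,
                               solanum_space)
        assert np.isinf(got.value)


class TestCustomBuilderContract:
    def test_solanum_builder_passes_through(self, solanum_space, oracle):
        def my_builder(theta, space):
            return ck.build_q_solanum(ck.SolanumParams.from_array(theta),
                                      space)
        tree = ck.read_newick("(A:2.0,B:1.0);")
        data = ck.TipObservations({"A": (12, "H"), "B": (24, "W")})
        theta = np.log([0.1, 0.01, 0.05, 0.02, 0.3, 0.4])
        got = ck.negloglik(tree, data, my_builder, theta, solanum_space)
        assert np.isfinite(got.value)

    def test_negative_off_diagonal_rejected(self, solanum_space):
        import scipy.sparse as sp

        def bad(theta, space):
            m = np.zeros((10, 10))
            m[0, 1], m[0, 0] = -1.0, 1.0
            return ck.RateMatrix(space, sp.csr_matrix(m))
        tree = ck.read_newick("(A:2.0,B:1.0);")
        data = ck.TipObservations({"A": (12, "H"), "B": (24, "W")})
        with pytest.raises(ck.ModelDefinitionError, match="row 0"):
            ck.negloglik(tree, data, bad, np.zeros(1), solanum_space)

    def test_nonzero_row_sums_rejected(self, solanum_space):
        import scipy.sparse as sp

        def bad(theta, space):
            m = np.zeros((10, 10))
            m[4, 5] = 1.0  # diagonal never closed
            return ck.RateMatrix(space, sp.csr_matrix(m))
        tree = ck.read_newick("(A:2.0,B:1.0);")
        data = ck.TipObservations({"A": (12, "H"), "B": (24, "W")})
        with pytest.raises(ck.ModelDefinitionError, match="row 4"):
            ck.negloglik(tree, data, bad, np.zeros(1), solanum_space)
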