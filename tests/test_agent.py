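"""Inference core: likelihood remapping, state inference, EFE, policy softmax.

The expected-free-energy and state-inference implementations are checked
against independent brute-force enumerations written directly from the
defining sums (nested Python loops over states/outcomes/policies).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antforage import (
    ConfigurationError,
    LogicError,
    build_preferences,
    build_tmaze,
    expected_free_energy,
    infer_states,
    local_window,
    make_reallocation_matrix,
    make_transition_set,
    policy_posterior,
    remap_likelihood,
    sample_action,
    select_action,
)

FLOOR = 1e-16


# -- independent brute-force oracles ----------------------------------------


def efe_bruteforce(A, B, C, qs):
    """Enumerate G(pi) = risk + ambiguity term by term from the definition."""
    n_pi, n_s, n_o = B.shape[0], B.shape[1], A.shape[0]
    G = np.zeros(n_pi)
    for pi in range(n_pi):
        qs_pi = np.zeros(n_s)
        for s2 in range(n_s):
            for s1 in range(n_s):
                qs_pi[s2] += B[pi][s2, s1] * qs[s1]
        qo_pi = np.zeros(n_o)
        for o in range(n_o):
            for s in range(n_s):
                qo_pi[o] += A[o, s] * qs_pi[s]
        risk = 0.0
        for o in range(n_o):
            risk += qo_pi[o] * (
                np.log(max(qo_pi[o], FLOOR)) - np.log(max(C[o], FLOOR))
            )
        ambiguity = 0.0
        for s in range(n_s):
            H = -sum(
                A[o, s] * np.log(max(A[o, s], FLOOR)) for o in range(n_o)
            )
            ambiguity += qs_pi[s] * H
        G[pi] = risk + ambiguity
    return G


def posterior_bruteforce(A, D, obs):
    """Bayes rule by hand: q(s) ∝ D(s) * A[obs, s] with the same floors."""
    w = np.maximum(D, FLOOR) * np.maximum(A[obs - 1, :], FLOOR)
    return w / w.sum()


def random_model(rng):
    A = rng.dirichlet(np.ones(10), size=9).T  # columns stochastic
    B = rng.dirichlet(np.ones(9), size=(9, 9)).transpose(0, 2, 1)
    C = rng.dirichlet(np.ones(10))
    D = rng.dirichlet(np.ones(9))
    qs = rng.dirichlet(np.ones(9))
    return A, B, C, D, qs


# -- likelihood remapping ----------------------------------------------------


class TestRemapLikelihood:
    def test_uniform_window(self):
        A = remap_likelihood(np.ones(9, dtype=int))
        assert A.shape == (10, 9)
        assert (A[0] == 1).all() and A.sum() == 9

    def test_single_hot_column(self):
        levels = np.array([1, 1, 1, 10, 1, 1, 1, 1, 1])
        A = remap_likelihood(levels)
        assert A[9, 3] == 1.0 and A[0, 3] == 0.0
        assert (A[0, [0, 1, 2, 4, 5, 6, 7, 8]] == 1.0).all()

    def test_matches_reallocation_matrix_rows(self):
        """A is the 3x3 patch of the environment likelihood, transposed."""
        arena = build_tmaze()
        rng = np.random.default_rng(5)
        walk = np.argwhere(arena.walkable)
        for r, c in walk[rng.choice(len(walk), 20)]:
            arena.pheromone[r, c] = rng.integers(1, 11)
        R = make_reallocation_matrix(arena)
        pos = (20, 19)
        levels, feasible = local_window(arena, pos)
        A = remap_likelihood(levels)
        nbr, _ = arena._neighbor_tables()
        window_rows = nbr[arena.flat_index(pos)]
        np.testing.assert_array_equal(A, R[window_rows].T)

    @pytest.mark.parametrize("bad", [0, 11, -3])
    def test_out_of_range_level_rejected(self, bad):
        levels = np.ones(9, dtype=int)
        levels[4] = bad
        with pytest.raises(LogicError):
            remap_likelihood(levels)


# -- preferences -------------------------------------------------------------


class TestPreferences:
    def test_flat_is_uniform(self):
        np.testing.assert_allclose(build_preferences("flat"), 0.1)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 2.0])
    def test_strict_monotone_increasing(self, alpha):
        C = build_preferences("strict", alpha)
        assert (np.diff(C) > 0).all()
        assert C.sum() == pytest.approx(1.0, abs=1e-12)

    def test_strict_slope_ratio(self):
        C = build_preferences("strict", alpha=0.5)
        assert C[9] / C[0] == pytest.approx(np.exp(4.5), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            build_preferences("bimodal")
        with pytest.raises(ConfigurationError):
            build_preferences("strict", alpha=0.0)


# -- state inference ---------------------------------------------------------


class TestInferStates:
    def test_uninformative_likelihood_returns_prior(self, rng):
        A = np.full((10, 9), 0.1)
        D = rng.dirichlet(np.ones(9))
        np.testing.assert_allclose(infer_states(A, D, 4), D, atol=1e-12)

    def test_single_consistent_column(self):
        levels = np.array([1, 1, 7, 1, 1, 1, 1, 1, 1])
        A = remap_likelihood(levels)
        qs = infer_states(A, np.full(9, 1 / 9), 7)
        expected = np.zeros(9)
        expected[2] = 1.0
        np.testing.assert_allclose(qs, expected, atol=1e-12)

    def test_k_consistent_columns_split_evenly(self):
        levels = np.array([3, 1, 3, 1, 3, 1, 1, 1, 1])  # k = 3 columns at level 3
        A = remap_likelihood(levels)
        qs = infer_states(A, np.full(9, 1 / 9), 3)
        expected = np.where(levels == 3, 1 / 3, 0.0)
        np.testing.assert_allclose(qs, expected, atol=1e-12)

    def test_matches_bayes_bruteforce_on_random_models(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            A, _, _, D, _ = random_model(rng)
            obs = int(rng.integers(1, 11))
            np.testing.assert_allclose(
                infer_states(A, D, obs), posterior_bruteforce(A, D, obs), atol=1e-10
            )

    def test_invalid_observation(self):
        with pytest.raises(LogicError):
            infer_states(np.full((10, 9), 0.1), np.full(9, 1 / 9), 11)


# -- expected free energy ----------------------------------------------------


class TestExpectedFreeEnergy:
    def test_flat_preferences_score_all_policies_equally(self):
        """One-hot sensing + flat C: risk is constant, ambiguity zero."""
        levels = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9])
        A = remap_likelihood(levels)
        qs = np.eye(9)[0]
        G = expected_free_energy(A, make_transition_set(), build_preferences("flat"), qs)
        np.testing.assert_allclose(G, G[0], atol=1e-12)

    def test_deterministic_sensing_reduces_to_neg_log_preference(self):
        levels = np.array([1, 4, 2, 10, 1, 6, 3, 1, 9])
        A = remap_likelihood(levels)
        C = build_preferences("strict", 0.5)
        qs = np.eye(9)[0]
        G = expected_free_energy(A, make_transition_set(), C, qs)
        np.testing.assert_allclose(G, -np.log(C[levels - 1]), atol=1e-10)

    def test_densest_neighbour_has_strictly_minimal_G(self):
        levels = np.array([2, 1, 1, 10, 1, 2, 1, 3, 1])
        A = remap_likelihood(levels)
        C = build_preferences("strict", 0.5)
        G = expected_free_energy(A, make_transition_set(), C, np.eye(9)[0])
        assert np.argmin(G) == 3
        assert (np.delete(G, 3) > G[3] + 1e-9).all()

    def test_matches_bruteforce_on_random_models(self):
        """Oracle equivalence on fully random (non-one-hot) models."""
        rng = np.random.default_rng(7)
        for _ in range(250):
            A, B, C, _, qs = random_model(rng)
            np.testing.assert_allclose(
                expected_free_energy(A, B, C, qs),
                efe_bruteforce(A, B, C, qs),
                atol=1e-10,
            )


# -- policy posterior and action sampling ------------------------------------


class TestPolicyPosterior:
    def test_uniform_when_scores_tie(self):
        qpi = policy_posterior(np.zeros(9), np.ones(9, bool), gamma=1.0)
        np.testing.assert_allclose(qpi, 1 / 9)

    def test_log2_bonus_doubles_probability(self):
        bonus = np.zeros(9)
        bonus[4] = np.log(2.0)
        qpi = policy_posterior(np.zeros(9), np.ones(9, bool), 1.0, bonus)
        assert qpi[4] == pytest.approx(2 / 10, rel=1e-12)
        assert qpi[0] == pytest.approx(1 / 10, rel=1e-12)

    def test_high_gamma_approaches_argmin(self, rng):
        G = rng.normal(size=9)
        qpi = policy_posterior(G, np.ones(9, bool), gamma=1e6)
        assert np.argmax(qpi) == np.argmin(G)
        assert qpi[np.argmin(G)] > 1 - 1e-9

    def test_infeasible_policies_get_zero_mass(self):
        feasible = np.ones(9, bool)
        feasible[[2, 5]] = False
        qpi = policy_posterior(np.zeros(9), feasible)
        assert qpi[2] == 0 and qpi[5] == 0
        assert qpi.sum() == pytest.approx(1.0)

    def test_no_feasible_policy_is_an_error(self):
        with pytest.raises(LogicError):
            policy_posterior(np.zeros(9), np.zeros(9, bool))

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_precision_monotonicity(self, seed, gamma):
        """Raising gamma never lowers the probability of the argmin-G policy."""
        r = np.random.default_rng(seed)
        G = r.normal(size=9)
        feasible = r.random(9) < 0.8
        feasible[0] = True  # "stay" is always available
        best = np.argmin(np.where(feasible, G, np.inf))
        p_lo = policy_posterior(G, feasible, gamma)[best]
        p_hi = policy_posterior(G, feasible, gamma * 2)[best]
        assert p_hi >= p_lo - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_normalisation_invariants(self, seed):
        r = np.random.default_rng(seed)
        A, B, C, D, qs_in = random_model(r)
        obs = int(r.integers(1, 11))
        qs = infer_states(A, D, obs)
        G = expected_free_energy(A, B, C, qs)
        qpi = policy_posterior(G, np.ones(9, bool), 1.0)
        assert qs.sum() == pytest.approx(1.0, abs=1e-12)
        assert qpi.sum() == pytest.approx(1.0, abs=1e-12)
        assert (qs >= 0).all() and (qpi >= 0).all()


class TestActionSampling:
    def test_one_hot_distribution_is_deterministic(self, rng):
        qpi = np.eye(9)[6]
        assert all(sample_action(qpi, rng) == 6 for _ in range(50))

    def test_uniform_sampling_frequencies(self):
        rng = np.random.default_rng(31)
        n = 90_000
        counts = np.bincount(
            [sample_action(np.full(9, 1 / 9), rng) for _ in range(n)], minlength=9
        )
        expect = n / 9
        tol = 4 * np.sqrt(n * (1 / 9) * (8 / 9))
        assert (np.abs(counts - expect) < tol).all()

    def test_fixed_seed_reproduces_draws(self):
        qpi = np.array([0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05])
        r1, r2 = np.random.default_rng(11), np.random.default_rng(11)
        seq1 = [sample_action(qpi, r1) for _ in range(200)]
        seq2 = [sample_action(qpi, r2) for _ in range(200)]
        assert seq1 == seq2

    def test_argmax_mode(self, rng):
        qpi = np.array([0.05, 0.4, 0.05, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05])
        assert select_action(qpi, rng, "argmax") == 1
        with pytest.raises(ConfigurationError):
            select_action(qpi, rng, "greedy")
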