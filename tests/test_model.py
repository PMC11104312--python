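"""Unit and property tests for the single-trial generative model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandit_aif.model import (
    DirichletBeliefs,
    InvalidBeliefsError,
    InvalidParameterError,
    action_distribution,
    build_preferences,
    evaluate_policies,
    expected_free_energy,
    information_gain,
    update_beliefs,
)


def scalar_efe_oracle(counts, c_r):
    """Outcome-by-outcome scalar evaluation of the two-term G formula."""
    import math

    z = math.exp(0.0) + math.exp(c_r) + math.exp(0.0)
    log_c = {"win": c_r - math.log(z), "loss": 0.0 - math.log(z)}
    g = []
    for k in range(3):
        a_win, a_loss = counts[0][k], counts[1][k]
        tot = a_win + a_loss
        gain = 0.0
        pragmatic = 0.0
        for o, a_o in (("win", a_win), ("loss", a_loss)):
            abar = a_o / tot
            gain += abar * 0.5 * (1.0 / a_o - 1.0 / tot)
            pragmatic += abar * log_c[o]
        g.append(-gain - pragmatic)
    return np.array(g)


class TestPreferences:
    def test_zero_reward_sensitivity_gives_uniform_prefs(self):
        prefs = build_preferences(0.0)
        assert np.allclose(prefs.log_prefs, np.log(1 / 3))

    def test_win_loss_log_preference_gap_equals_reward_sensitivity(self):
        # softmax then log forces log p(win) - log p(loss) = c_r exactly
        prefs = build_preferences(4.0)
        assert prefs.log_prefs[1] - prefs.log_prefs[2] == pytest.approx(4.0, abs=1e-12)
        assert np.exp(prefs.log_prefs).sum() == pytest.approx(1.0)

    def test_preference_mass_on_win_increases_with_reward_sensitivity(self):
        p2 = np.exp(build_preferences(2.0).log_prefs[1])
        p4 = np.exp(build_preferences(4.0).log_prefs[1])
        assert p2 < p4

    def test_nonfinite_reward_sensitivity_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_preferences(np.nan)


class TestExpectedFreeEnergy:
    def test_equal_counts_give_equal_efe(self):
        beliefs = DirichletBeliefs.fresh(0.25)
        g = expected_free_energy(beliefs, build_preferences(4.0))
        assert np.allclose(g, g[0])

    def test_reward_evidence_lowers_efe(self):
        # arm 1 has seen a win; with strong reward preference it must be
        # preferred over fresh arms, which stay exactly tied
        counts = np.array([[1.25, 0.25, 0.25], [0.25, 0.25, 0.25]])
        g = expected_free_energy(DirichletBeliefs(counts), build_preferences(4.0))
        oracle = scalar_efe_oracle(counts.tolist(), 4.0)
        assert np.allclose(g, oracle, atol=1e-12)
        assert g[0] < g[1] == pytest.approx(g[2], abs=1e-12)

    def test_pure_information_seeking_avoids_well_known_arms(self):
        # c_r = 0: preferences flat, only the novelty term differentiates
        counts = np.array([[5.0, 0.25, 0.25], [5.0, 0.25, 0.25]])
        g = expected_free_energy(DirichletBeliefs(counts), build_preferences(0.0))
        oracle = scalar_efe_oracle(counts.tolist(), 0.0)
        assert np.allclose(g, oracle, atol=1e-12)
        assert g[0] > g[1]

    def test_matches_scalar_oracle_on_random_beliefs(self, rng):
        prefs = build_preferences(3.0)
        for _ in range(100):
            counts = rng.uniform(0.1, 8.0, size=(2, 3))
            g = expected_free_energy(DirichletBeliefs(counts), prefs)
            assert np.allclose(g, scalar_efe_oracle(counts.tolist(), 3.0), atol=1e-10)

    @pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")
    def test_exact_expected_kl_matches_numerical_beta_kl(self, rng):
        # with two outcomes each arm's Dirichlet is a Beta, so the exact
        # expected-KL novelty can be cross-checked by numerical integration
        from scipy.integrate import quad
        from scipy.stats import beta as beta_dist

        def beta_kl(a_new, b_new, a, b):
            f_new = beta_dist(a_new, b_new)
            f_old = beta_dist(a, b)
            val, _ = quad(lambda x: f_new.pdf(x) * (f_new.logpdf(x) - f_old.logpdf(x)), 0, 1)
            return val

        for _ in range(5):
            counts = rng.uniform(0.2, 6.0, size=(2, 3))
            exact = information_gain(counts, exact=True)
            for k in range(3):
                a, b = counts[0, k], counts[1, k]
                expected = (a / (a + b)) * beta_kl(a + 1, b, a, b) + (b / (a + b)) * beta_kl(a, b + 1, a, b)
                assert exact[k] == pytest.approx(expected, abs=1e-8)

    def test_exact_and_bound_novelty_both_shrink_with_experience(self, rng):
        # both novelty variants must assign less information value to an
        # arm as its counts scale up
        for _ in range(20):
            counts = rng.uniform(0.2, 6.0, size=(2, 3))
            grown = counts * np.array([1.0, 4.0, 1.0])
            for exact in (False, True):
                before = information_gain(counts, exact=exact)
                after = information_gain(grown, exact=exact)
                assert np.all(before > 0) and np.all(after > 0)
                assert after[1] < before[1]

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(InvalidBeliefsError):
            expected_free_energy(np.array([[0.0, 1, 1], [1, 1, 1.0]]), build_preferences(1.0))

    def test_arm_permutation_equivariance(self, rng):
        prefs = build_preferences(2.5)
        counts = rng.uniform(0.2, 5.0, size=(2, 3))
        perm = np.array([2, 0, 1])
        g = expected_free_energy(DirichletBeliefs(counts), prefs)
        g_perm = expected_free_energy(DirichletBeliefs(counts[:, perm]), prefs)
        assert np.allclose(g[perm], g_perm)

    def test_information_gain_shrinks_as_counts_grow(self):
        # with flat preferences an arm's G rises as its counts scale up
        prefs = build_preferences(0.0)
        gs = []
        for scale in (0.5, 1.0, 2.0, 8.0):
            counts = np.array([[scale, 1.0, 1.0], [scale, 1.0, 1.0]])
            gs.append(expected_free_energy(DirichletBeliefs(counts), prefs)[0])
        assert np.all(np.diff(gs) > 0)

    def test_larger_a0_shrinks_information_gain_spread(self):
        # same observation history on top of low vs high initial counts
        obs = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5]])
        spread = []
        for a0 in (0.25, 5.0):
            gain = information_gain(np.full((2, 3), a0) + obs)
            spread.append(gain.max() - gain.min())
        assert spread[1] < spread[0]


class TestActionDistribution:
    def test_zero_precision_limit_is_uniform(self):
        probs = action_distribution(np.array([0.3, 5.0, -2.0]), 0.0)
        assert np.allclose(probs, 1 / 3)

    def test_softmax_values(self):
        probs = action_distribution(np.array([0.0, 1.0, 2.0]), 1.0)
        assert np.allclose(probs, [0.6652, 0.2447, 0.0900], atol=1e-3)

    def test_shift_invariance(self, rng):
        efe = rng.standard_normal(3)
        assert np.allclose(
            action_distribution(efe, 2.0), action_distribution(efe + 7.3, 2.0)
        )

    def test_nan_efe_rejected(self):
        with pytest.raises(InvalidParameterError):
            action_distribution(np.array([0.0, np.nan, 1.0]), 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-20, 20), min_size=3, max_size=3),
        st.floats(0.01, 10.0),
    )
    def test_normalization_and_positivity(self, efe, alpha):
        probs = action_distribution(np.array(efe), alpha)
        assert abs(probs.sum() - 1.0) < 1e-12
        assert np.all(probs > 0)
        # strictly interior whenever the exponents stay well-conditioned
        if alpha * (max(efe) - min(efe)) < 30:
            assert np.all(probs < 1)

    def test_policy_and_action_distributions_consistent(self):
        beliefs = DirichletBeliefs(np.array([[1.5, 0.3, 0.25], [0.4, 0.9, 0.25]]))
        pe = evaluate_policies(beliefs, build_preferences(4.0), 2.0)
        assert pe.policy_dist.sum() == pytest.approx(1.0, abs=1e-12)
        assert pe.action_dist.sum() == pytest.approx(1.0, abs=1e-12)
        # equal G implies uniform distributions
        pe_flat = evaluate_policies(DirichletBeliefs.fresh(0.5), build_preferences(4.0), 2.0)
        assert np.allclose(pe_flat.policy_dist, 1 / 3)
        assert np.allclose(pe_flat.action_dist, 1 / 3)


class TestBeliefUpdate:
    def test_single_win_increments_only_its_cell(self):
        fresh = DirichletBeliefs.fresh(0.25)
        new = update_beliefs(fresh, arm=2, outcome="win", learning_rate_win=0.5, learning_rate_loss=0.3)
        expected = np.full((2, 3), 0.25)
        expected[0, 1] = 0.75
        assert np.allclose(new.counts, expected)
        # input untouched
        assert np.allclose(fresh.counts, 0.25)

    def test_zero_loss_rate_freezes_beliefs_on_losses(self):
        fresh = DirichletBeliefs.fresh(0.25)
        new = update_beliefs(fresh, arm=1, outcome="loss", learning_rate_win=0.5, learning_rate_loss=0.0)
        assert np.allclose(new.counts, fresh.counts)

    def test_count_mass_conservation(self):
        beliefs = DirichletBeliefs.fresh(0.25)
        for t in range(16):
            outcome = "win" if t % 2 == 0 else "loss"
            beliefs = update_beliefs(beliefs, 3, outcome, 1.0, 1.0)
        assert beliefs.counts.sum() == pytest.approx(6 * 0.25 + 16)

    def test_invalid_arm_rejected(self):
        with pytest.raises(ValueError):
            update_beliefs(DirichletBeliefs.fresh(1.0), 4, "win", 0.5, 0.5)
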