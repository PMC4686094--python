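"""Tests of the agent update rules and choice policies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.agents import (DETERMINISTIC_RC_POLICY, LatentStateAgent,
                            ModelBasedAgent, QLambdaAgent, RewardAsCueAgent,
                            cue_index, latent_state_choice_probs,
                            latent_state_update, make_agent,
                            perseveration_bonus, softmax_choice_probs)
from twostep.task_env import TaskConfig, TrialEvents

REDUCED = TaskConfig.reduced()
ORIGINAL = TaskConfig.original()


def events(choice1, common, outcome, choice2=0):
    second_state = choice1 if common else 1 - choice1
    return TrialEvents(choice1=choice1, common=common,
                       second_state=second_state, choice2=choice2,
                       outcome=outcome)


class TestSoftmax:
    def test_equal_values_give_equal_probabilities(self):
        assert np.allclose(softmax_choice_probs([0.5, 0.5], 3.7), [0.5, 0.5])

    def test_zero_inverse_temperature_is_uniform(self):
        assert np.allclose(softmax_choice_probs([1.0, 0.0], 0.0), [0.5, 0.5])

    def test_hand_computed_example(self):
        # exp(4) / (exp(4) + exp(1)) for values (0.8, 0.2) at T = 5
        expected = math.exp(4) / (math.exp(4) + math.exp(1))
        p = softmax_choice_probs([0.8, 0.2], 5.0)
        assert np.allclose(p, [expected, 1 - expected], atol=1e-12)

    def test_overflow_safe(self):
        p = softmax_choice_probs([1e4, 0.0], 100.0)
        assert np.isfinite(p).all() and abs(p.sum() - 1) < 1e-12

    def test_rejects_non_finite_values_and_negative_temperature(self):
        with pytest.raises(ValueError):
            softmax_choice_probs([np.nan, 0.0], 1.0)
        with pytest.raises(ValueError):
            softmax_choice_probs([0.1, 0.2], -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(v0=st.floats(-10, 10), v1=st.floats(-10, 10),
           T=st.floats(0, 50))
    def test_normalisation_and_monotonicity(self, v0, v1, T):
        p = softmax_choice_probs([v0, v1], T)
        assert p.min() > 0 and abs(p.sum() - 1) < 1e-9
        if v0 > v1:
            assert p[0] >= 0.5
        if v0 < v1:
            assert p[1] >= 0.5


class TestQLambda:
    def test_lambda_one_uses_only_outcome(self):
        # first-step update reduces to (1 - a) Q + a r, independent of Q2
        for r in (0, 1):
            ag = QLambdaAgent(alpha=0.3, T=2.0, lam=1.0)
            ag.reset(REDUCED)
            ag.q2[0, 0] = 0.9  # should not matter
            ag.update(events(0, True, r))
            assert ag.q1[0] == pytest.approx(0.7 * 0.5 + 0.3 * r)

    def test_lambda_zero_uses_only_second_step_value(self):
        ag = QLambdaAgent(alpha=0.4, T=2.0, lam=0.0)
        ag.reset(REDUCED)
        ag.q2[1, 0] = 0.9
        ag.update(events(0, False, outcome=0))  # rare: A -> state b
        # independent of the outcome, driven by pre-update Q(s2)
        assert ag.q1[0] == pytest.approx(0.6 * 0.5 + 0.4 * 0.9)

    def test_zero_learning_rate_freezes_values(self):
        ag = QLambdaAgent(alpha=0.0, T=2.0, lam=0.5)
        ag.reset(REDUCED)
        for t in range(10):
            ag.update(events(t % 2, True, t % 2))
        assert np.all(ag.q1 == 0.5) and np.all(ag.q2 == 0.5)

    def test_first_step_update_uses_pre_update_second_step_value(self):
        # sequential ordering: Q1 update sees Q2 before its own update
        ag = QLambdaAgent(alpha=0.5, T=1.0, lam=0.5)
        ag.reset(REDUCED)
        ag.q2[0, 0] = 0.8
        ag.update(events(0, True, 1))
        # Q1 <- 0.5*0.5 + 0.5*(0.8 + 0.5*(1 - 0.8)) with the OLD q2
        assert ag.q1[0] == pytest.approx(0.25 + 0.5 * 0.9)
        assert ag.q2[0, 0] == pytest.approx(0.9)

    def test_only_chosen_values_change(self):
        ag = QLambdaAgent(alpha=0.5, T=1.0, lam=1.0)
        ag.reset(ORIGINAL)
        ag.update(TrialEvents(choice1=0, common=True, second_state=0,
                              choice2=1, outcome=1))
        assert ag.q1[1] == 0.5
        assert ag.q2[0, 0] == 0.5 and ag.q2[1, 0] == 0.5
        assert ag.q2[0, 1] != 0.5

    @settings(derandomize=True, max_examples=30)
    @given(alpha=st.floats(0, 1), lam=st.floats(0, 1),
           seed=st.integers(0, 10_000))
    def test_q_values_stay_in_unit_interval(self, alpha, lam, seed):
        # all updates are convex combinations of quantities in [0, 1]
        rng = np.random.default_rng(seed)
        ag = QLambdaAgent(alpha=alpha, T=3.0, lam=lam)
        ag.reset(ORIGINAL)
        for _ in range(200):
            ag.update(events(int(rng.integers(2)), bool(rng.integers(2)),
                             int(rng.integers(2)), int(rng.integers(2))))
        assert 0 <= ag.q1.min() and ag.q1.max() <= 1
        assert 0 <= ag.q2.min() and ag.q2.max() <= 1


class TestModelBased:
    def test_equal_state_values_conserve(self):
        ag = ModelBasedAgent(alpha=0.5, T=5.0)
        ag.reset(REDUCED)
        ag.q2[:, 0] = 0.7
        assert np.allclose(ag.first_step_values(), [0.7, 0.7])

    def test_hand_expanded_weighted_sum(self):
        # p_common = 0.8, V = (0.8, 0.2): Q1 = (0.68, 0.32)
        ag = ModelBasedAgent(alpha=0.5, T=5.0)
        ag.reset(REDUCED)
        ag.q2[0, 0], ag.q2[1, 0] = 0.8, 0.2
        assert np.allclose(ag.first_step_values(), [0.68, 0.32])

    def test_original_task_state_value_is_max_of_actions(self):
        ag = ModelBasedAgent(alpha=0.5, T=5.0)
        ag.reset(ORIGINAL)
        ag.q2[0] = [0.6, 0.9]
        ag.q2[1] = [0.3, 0.1]
        v = ag.first_step_values()
        assert v[0] == pytest.approx(0.7 * 0.9 + 0.3 * 0.3)
        assert v[1] == pytest.approx(0.3 * 0.9 + 0.7 * 0.3)

    def test_transition_learning_matches_ema_oracle(self):
        # independent exponential-moving-average oracle
        eta = 0.5
        ag = ModelBasedAgent(alpha=0.5, T=5.0, eta=eta)
        ag.reset(REDUCED)
        observed = [0, 1, 1, 0, 1, 0, 0, 1, 1, 1]
        est = 0.5  # P(state a | action A)
        for s2 in observed:
            ag.update(TrialEvents(choice1=0, common=(s2 == 0),
                                  second_state=s2, choice2=0, outcome=0))
            est = (1 - eta) * est + eta * (1.0 if s2 == 0 else 0.0)
            assert ag.t_hat[0, 0] == pytest.approx(est)
            assert ag.t_hat[0].sum() == pytest.approx(1.0)
            # unchosen action's row untouched
            assert np.allclose(ag.t_hat[1], [0.5, 0.5])

    def test_eta_one_tracks_most_recent_transition(self):
        ag = ModelBasedAgent(alpha=0.5, T=5.0, eta=1.0)
        ag.reset(REDUCED)
        ag.update(events(0, False, 0))  # A -> b
        assert np.allclose(ag.t_hat[0], [0.0, 1.0])
        ag.update(events(0, True, 0))   # A -> a
        assert np.allclose(ag.t_hat[0], [1.0, 0.0])

    def test_eta_zero_never_updates(self):
        ag = ModelBasedAgent(alpha=0.5, T=5.0, eta=0.0)
        ag.reset(REDUCED)
        for _ in range(5):
            ag.update(events(0, True, 1))
        assert np.allclose(ag.t_hat, 0.5)


class TestRewardAsCue:
    def test_first_trial_has_no_cue_and_uniform_choice(self):
        ag = RewardAsCueAgent(alpha=0.2, T=4.0)
        ag.reset(REDUCED)
        assert np.allclose(ag.first_step_probs(), [0.5, 0.5])
        ag.update(events(0, True, 1))
        assert ag.cue == cue_index(1, 0)
        assert np.all(ag.q1 == 0.5)  # no first-step update on trial 1

    def test_zero_first_step_learning_rate(self):
        ag = RewardAsCueAgent(alpha=0.0, T=4.0)
        ag.reset(REDUCED)
        for t in range(20):
            ag.update(events(t % 2, True, (t // 2) % 2))
        assert np.all(ag.q1 == 0.5)

    def test_deterministic_environment_converges_geometrically(self):
        # reward always in state a, always common: cue (1, a) value of the
        # chosen action follows the EMA closed form 1 + (0.5 - 1)(1-a)^k
        alpha = 0.3
        ag = RewardAsCueAgent(alpha=alpha, T=4.0)
        ag.reset(REDUCED)
        ag.update(events(0, True, 1))  # trial 1 sets the cue
        cue = cue_index(1, 0)
        for k in range(1, 15):
            ag.update(events(0, True, 1))
            expected = 1 + (0.5 - 1) * (1 - alpha) ** k
            assert ag.q1[cue, 0] == pytest.approx(expected)

    def test_learns_the_reward_as_cue_policy_on_reduced_blocks(self):
        # after extended experience of the blocks task the greedy policy in
        # each cue state matches: reward in a -> A, reward in b -> B,
        # non-reward in a -> B, non-reward in b -> A
        from twostep.simulate import run_session
        sess = run_session(make_agent("reward_as_cue", alpha=0.05, T=4.0),
                           REDUCED, 10000, seed=99)
        ag = RewardAsCueAgent(alpha=0.05, T=4.0)
        ag.reset(REDUCED)
        for t in range(sess.n_trials):
            ag.update(sess.events(t))
        for cue, action in DETERMINISTIC_RC_POLICY.items():
            assert int(np.argmax(ag.q1[cue])) == action


class TestLatentState:
    def test_two_hypothesis_bayes_rule_by_hand(self):
        ev = events(0, True, 1)  # reward in state a
        post = latent_state_update(0.5, ev, p_good=0.8, p_bad=0.2, omega=0.0)
        assert post == pytest.approx(0.8 / (0.8 + 0.2))

    def test_non_reward_is_evidence_against(self):
        ev = events(0, True, 0)  # no reward in state a
        post = latent_state_update(0.5, ev, p_good=0.8, p_bad=0.2, omega=0.0)
        assert post == pytest.approx(0.2 / (0.2 + 0.8))

    def test_maximal_mixing_pins_posterior_to_half(self):
        for r in (0, 1):
            post = latent_state_update(0.9, events(0, True, r),
                                       p_good=0.8, p_bad=0.2, omega=0.5)
            assert post == pytest.approx(0.5)

    def test_uninformative_likelihood_leaves_posterior(self):
        for p0 in (0.3, 0.5, 0.8):
            post = latent_state_update(p0, events(1, True, 1),
                                       p_good=0.5, p_bad=0.5, omega=0.0)
            assert post == pytest.approx(p0)

    def test_choice_rule(self):
        assert np.allclose(latent_state_choice_probs(0.9, 0.188),
                           [0.812, 0.188])
        assert np.allclose(latent_state_choice_probs(0.1, 0.188),
                           [0.188, 0.812])
        assert np.allclose(latent_state_choice_probs(0.5, 0.188), [0.5, 0.5])
        assert np.allclose(latent_state_choice_probs(0.9, 0.5), [0.5, 0.5])

    @settings(derandomize=True, max_examples=30)
    @given(omega=st.floats(0, 1), seed=st.integers(0, 10_000))
    def test_posterior_stays_in_unit_interval(self, omega, seed):
        rng = np.random.default_rng(seed)
        ag = LatentStateAgent(omega=omega, epsilon=0.2)
        ag.reset(REDUCED)
        for _ in range(200):
            ag.update(events(int(rng.integers(2)), bool(rng.integers(2)),
                             int(rng.integers(2))))
            assert 0.0 <= ag.posterior <= 1.0

    def test_default_beliefs_follow_task_variant(self):
        ag = LatentStateAgent(omega=0.05, epsilon=0.2)
        ag.reset(REDUCED)
        assert (ag.p_good, ag.p_bad) == (0.8, 0.2)
        ag.reset(ORIGINAL)
        assert (ag.p_good, ag.p_bad) == (0.625, 0.375)


class TestPerseveration:
    def test_zero_bias_changes_nothing(self):
        assert np.allclose(perseveration_bonus(0, 0.0), [0.0, 0.0])
        assert np.allclose(perseveration_bonus(None, 0.4), [0.0, 0.0])

    def test_stay_probability_on_value_tied_trials(self):
        # p = 0.4, equal values, T = 5: P(stay) = e^2 / (e^2 + 1)
        ag = QLambdaAgent(alpha=0.0, T=5.0, lam=1.0, perseveration=0.4)
        ag.reset(REDUCED)
        ag.update(events(0, True, 1))  # previous choice A; values frozen
        p = ag.first_step_probs()
        assert p[0] == pytest.approx(math.exp(2) / (math.exp(2) + 1))

    def test_large_bias_forces_repetition(self):
        ag = QLambdaAgent(alpha=0.0, T=5.0, lam=1.0, perseveration=50.0)
        ag.reset(REDUCED)
        ag.update(events(1, True, 0))
        assert ag.first_step_probs()[1] > 0.999999

    def test_bias_never_enters_value_updates(self):
        ag = QLambdaAgent(alpha=0.5, T=5.0, lam=1.0, perseveration=0.4)
        ag.reset(REDUCED)
        ref = QLambdaAgent(alpha=0.5, T=5.0, lam=1.0, perseveration=0.0)
        ref.reset(REDUCED)
        for t in range(20):
            ev = events(t % 2, True, (t // 3) % 2)
            ag.update(ev)
            ref.update(ev)
        assert np.array_equal(ag.q1, ref.q1)
        assert np.array_equal(ag.q2, ref.q2)


def test_make_agent_registry_and_aliases():
    assert isinstance(make_agent("q0", alpha=0.5, T=3.0), QLambdaAgent)
    assert make_agent("q1", alpha=0.5, T=3.0).lam == 1.0
    assert make_agent("q0", alpha=0.5, T=3.0).lam == 0.0
    with pytest.raises(ValueError):
        make_agent("not_an_agent")
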