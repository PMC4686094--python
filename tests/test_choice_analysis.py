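"""Tests of stay probabilities, design codings and logistic regressions."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from twostep.agents import make_agent
from twostep.choice_analysis import (BASIC_PREDICTORS, build_design,
                                     build_lagged_design,
                                     fit_choice_regression,
                                     fit_lagged_regression,
                                     lagged_loading_matrix,
                                     predictor_correlation, stay_table,
                                     trial_start_value_table)
from twostep.simulate import run_batch, run_session
from twostep.task_env import TaskConfig

from conftest import make_session

REDUCED = TaskConfig.reduced()


class TestStayTable:
    def test_always_stay_agent_has_all_cells_one(self):
        # a huge perseveration bias makes the agent repeat trial 1's choice
        agent = make_agent("q_lambda", alpha=0.0, T=5.0, lam=1.0,
                           perseveration=100.0)
        sessions = run_batch(agent, REDUCED, 4, 2000, seed=1)
        table = stay_table(sessions)
        assert np.allclose(table.mean.values, 1.0)

    def test_hand_counted_six_trial_session(self):
        # events (choice1, common, outcome):
        #   t0 A common rew | t1 A rare  non | t2 B common non
        #   t3 B rare  rew  | t4 B common rew | t5 A common non
        sess = make_session(
            choice1=[0, 0, 1, 1, 1, 0],
            common=[1, 0, 1, 0, 1, 1],
            second_state=[0, 1, 1, 0, 1, 0],
            outcome=[1, 0, 0, 1, 1, 0])
        table = stay_table([sess])
        # previous-trial cells -> stay outcome at the next trial:
        # (common, rew): t0->stay(t1)=1, t4->stay(t5)=0 -> 0.5
        # (rare, non):   t1->stay(t2)=0 -> 0
        # (common, non): t2->stay(t3)=1 -> 1
        # (rare, rew):   t3->stay(t4)=1 -> 1
        assert table.mean[("common", "rewarded")] == pytest.approx(0.5)
        assert table.mean[("rare", "non-rewarded")] == pytest.approx(0.0)
        assert table.mean[("common", "non-rewarded")] == pytest.approx(1.0)
        assert table.mean[("rare", "rewarded")] == pytest.approx(1.0)

    def test_empty_cell_warns_and_is_excluded(self):
        sess = make_session(choice1=[0, 0, 0], common=[1, 1, 1],
                            second_state=[0, 0, 0], outcome=[1, 1, 1])
        with pytest.warns(UserWarning, match="no trials"):
            table = stay_table([sess])
        assert np.isnan(table.mean[("rare", "rewarded")])
        assert table.mean[("common", "rewarded")] == 1.0


class TestBuildDesign:
    def _session(self):
        # trial 0: A, common -> a, rewarded; probs a=0.8, b=0.2
        # trial 1: B, rare -> a, non-rewarded; probs a=0.2, b=0.8
        probs = np.empty((3, 2, 2))
        probs[0] = [[0.8, 0.8], [0.2, 0.2]]
        probs[1] = [[0.2, 0.2], [0.8, 0.8]]
        probs[2] = [[0.2, 0.2], [0.8, 0.8]]
        return make_session(choice1=[0, 1, 1], common=[1, 0, 1],
                            second_state=[0, 0, 1], outcome=[1, 0, 0],
                            reward_probs=probs)

    def test_one_back_codings(self):
        X, y = build_design(self._session(), BASIC_PREDICTORS)
        # row 0 looks back at trial 0 (rewarded common)
        assert list(X.iloc[0]) == [1.0, 0.5, 0.5, 0.5]
        # row 1 looks back at trial 1 (non-rewarded rare)
        assert list(X.iloc[1]) == [1.0, -0.5, -0.5, 0.5]
        assert list(y) == [0.0, 1.0]  # switch then stay

    def test_correct_predictors(self):
        X, _ = build_design(self._session(),
                            ["correct_binary", "correct_continuous"])
        # trial 0: chose A, common state a has p=0.8 vs b 0.2 -> correct
        assert X["correct_binary"].iloc[0] == 0.5
        assert X["correct_continuous"].iloc[0] == pytest.approx(0.6)
        # trial 1: chose B while b has p=0.8 -> correct again
        assert X["correct_binary"].iloc[1] == 0.5
        assert X["correct_continuous"].iloc[1] == pytest.approx(0.6)

    def test_event_type_predictors(self):
        X, _ = build_design(self._session(),
                            ["rewarded_common", "rewarded_rare",
                             "nonrewarded_common", "nonrewarded_rare"])
        assert list(X.iloc[0]) == [0.5, 0.0, 0.0, 0.0]
        assert list(X.iloc[1]) == [0.0, 0.0, 0.0, 0.5]

    def test_fixed_equal_probs_zero_continuous_correct(self):
        agent = make_agent("q1", alpha=0.334, T=3.22)
        sess = run_session(agent, TaskConfig.reduced_fixed((0.5, 0.5)),
                           500, seed=2)
        X, _ = build_design(sess, ["correct_continuous", "correct_binary"])
        assert np.all(X["correct_continuous"] == 0.0)
        assert np.all(X["correct_binary"] == 0.0)

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError, match="unknown predictor"):
            build_design(self._session(), ["bogus"])


class TestChoiceRegression:
    def test_recovers_known_logistic_rule(self):
        # agent staying by a known logistic rule of the coded predictors
        beta = np.array([0.3, 1.2, -0.4, 0.8])  # stay, outcome, trans, inter
        rng = np.random.default_rng(11)
        sessions = []
        for _ in range(10):
            n = 4000
            common = rng.random(n) < 0.8
            outcome = (rng.random(n) < 0.5).astype(int)
            choice1 = np.empty(n, dtype=np.int64)
            choice1[0] = 0
            for t in range(1, n):
                x = np.array([1.0,
                              0.5 if outcome[t - 1] else -0.5,
                              0.5 if common[t - 1] else -0.5,
                              0.5 if common[t - 1] == outcome[t - 1]
                              else -0.5])
                stay = rng.random() < expit(beta @ x)
                choice1[t] = choice1[t - 1] if stay else 1 - choice1[t - 1]
            second_state = np.where(common, choice1, 1 - choice1)
            sessions.append(make_session(choice1, common.astype(int),
                                         second_state, outcome))
        res = fit_choice_regression(sessions, BASIC_PREDICTORS)
        for b, name in zip(beta, BASIC_PREDICTORS):
            assert abs(res.mean[name] - b) < 3 * res.sem[name] + 0.02

    def test_saturated_model_recovers_stay_table(self):
        # the 4-predictor model is saturated on the 4 cells: its fitted
        # probabilities equal the empirical stay frequencies
        agent = make_agent("q1", alpha=0.334, T=3.22)
        sess = run_session(agent, REDUCED, 8000, seed=3)
        X, y = build_design(sess, BASIC_PREDICTORS)
        fit = sm.Logit(y, X).fit(disp=0)
        table = stay_table([sess]).mean
        for common, rew, cell in [(0.5, 0.5, ("common", "rewarded")),
                                  (0.5, -0.5, ("common", "non-rewarded")),
                                  (-0.5, 0.5, ("rare", "rewarded")),
                                  (-0.5, -0.5, ("rare", "non-rewarded"))]:
            x = np.array([1.0, rew, common, 0.5 if common == rew else -0.5])
            assert expit(fit.params @ x) == pytest.approx(table[cell],
                                                          abs=1e-6)

    def test_adding_correct_predictor_never_increases_deviance(self):
        agent = make_agent("q1", alpha=0.334, T=3.22)
        sess = run_session(agent, REDUCED, 5000, seed=4)
        X4, y = build_design(sess, BASIC_PREDICTORS)
        X5, _ = build_design(sess, list(BASIC_PREDICTORS) + ["correct_binary"])
        ll4 = sm.Logit(y, X4).fit(disp=0).llf
        ll5 = sm.Logit(y, X5).fit(disp=0).llf
        assert ll5 >= ll4 - 1e-8

    def test_interaction_vanishes_without_transition_or_value_structure(self):
        # constant equal reward probabilities: trial-start values carry no
        # information, so the spurious interaction disappears
        agent = make_agent("q1", alpha=0.334, T=3.22)
        sessions = run_batch(agent, TaskConfig.reduced_fixed((0.5, 0.5)),
                             10, 10000, seed=5)
        res = fit_choice_regression(sessions, BASIC_PREDICTORS)
        assert res.pvalues["interaction"] > 0.01
        assert abs(res.mean["interaction"]) < 0.05


class TestLaggedRegression:
    def test_lagged_design_encoding(self):
        sess = make_session(choice1=[0, 1, 1], common=[1, 1, 0],
                            second_state=[0, 1, 0], outcome=[1, 0, 1])
        X, y = build_lagged_design(sess, n_lags=2)
        # one usable trial (t=2), response: choice A?
        assert list(y) == [0.0]
        # lag 1 = trial 1: non-rewarded common, choice B -> sign -1
        assert X["nonrewarded_common_lag1"].iloc[0] == -0.5
        assert X["rewarded_common_lag1"].iloc[0] == 0.0
        # lag 2 = trial 0: rewarded common, choice A -> sign +1
        assert X["rewarded_common_lag2"].iloc[0] == 0.5

    def test_session_shorter_than_lags_rejected(self):
        sess = make_session(choice1=[0, 1], common=[1, 1],
                            second_state=[0, 1], outcome=[1, 0])
        with pytest.raises(ValueError, match="shorter"):
            build_lagged_design(sess, n_lags=5)

    def test_positive_loading_means_repeat(self):
        # an agent that mostly repeats its previous choice after reward
        # loads positively on lag-1 reward predictors
        agent = make_agent("q1", alpha=0.5, T=5.0)
        sessions = run_batch(agent, REDUCED, 5, 5000, seed=6)
        res = fit_lagged_regression(sessions, n_lags=3)
        assert res.mean["rewarded_common_lag1"] > 0
        mat = lagged_loading_matrix(res)
        assert mat.shape == (3, 4)


class TestValueTable:
    def test_requires_value_based_agent(self):
        agent = make_agent("latent_state", omega=0.03, epsilon=0.2)
        sessions = run_batch(agent, REDUCED, 2, 500, seed=7)
        with pytest.raises(ValueError, match="first-step action values"):
            trial_start_value_table(sessions)

    def test_zero_learning_rate_keeps_initial_values(self):
        agent = make_agent("q1", alpha=0.0, T=3.0)
        sessions = run_batch(agent, REDUCED, 3, 1000, seed=8)
        table = trial_start_value_table(sessions)
        assert np.allclose(table.mean["chosen"], 0.5)
        assert np.allclose(table.mean["not_chosen"], 0.5)

    def test_blocks_value_difference_shows_interaction(self, q1_reduced_batch):
        # chosen-minus-unchosen difference is larger on common-rewarded and
        # rare-non-rewarded trials (the mechanism behind the confound)
        table = trial_start_value_table(q1_reduced_batch)
        diff = table.mean["diff"]
        assert diff[("common", "rewarded")] > diff[("common", "non-rewarded")]
        assert diff[("rare", "non-rewarded")] > diff[("rare", "rewarded")]

    def test_equal_fixed_probs_equalise_cells(self):
        agent = make_agent("q1", alpha=0.334, T=3.22)
        sessions = run_batch(agent, TaskConfig.reduced_fixed((0.5, 0.5)),
                             10, 10000, seed=9)
        table = trial_start_value_table(sessions)
        diffs = table.per_session_diff()
        from scipy import stats
        interaction = (diffs[("common", "rewarded")]
                       - diffs[("rare", "rewarded")]
                       + diffs[("rare", "non-rewarded")]
                       - diffs[("common", "non-rewarded")])
        assert stats.ttest_1samp(interaction, 0.0).pvalue > 0.01


class TestPredictorCorrelation:
    def test_orthogonal_and_duplicated_predictors(self):
        # balanced hand-built patterns: previous-trial outcome and
        # transition codes are exactly orthogonal over the 8 used rows
        common = [1, 0, 1, 0, 1, 0, 1, 0, 1]
        choice1 = [0] * 9
        second_state = [0 if c else 1 for c in common]
        outcome = [1, 1, 0, 0, 1, 1, 0, 0, 1]
        sess = make_session(choice1, common, second_state, outcome)
        corr = predictor_correlation([sess], ["outcome", "transition"])
        assert abs(corr.loc["outcome", "transition"]) < 1e-9
        corr2 = predictor_correlation([sess], ["outcome", "outcome"])
        assert corr2.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_predictor_reported_nan(self):
        sess = make_session(choice1=[0, 1, 0, 1], common=[1, 1, 1, 1],
                            second_state=[0, 1, 0, 1], outcome=[1, 0, 1, 0])
        with pytest.warns(UserWarning, match="constant"):
            corr = predictor_correlation([sess], ["stay", "outcome"])
        assert np.isnan(corr.loc["stay", "outcome"])

    def test_interaction_correlates_with_correct_predictor(
            self, q1_reduced_batch):
        corr = predictor_correlation(q1_reduced_batch,
                                     ["interaction", "correct_binary"])
        assert corr.loc["interaction", "correct_binary"] > 0.1
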